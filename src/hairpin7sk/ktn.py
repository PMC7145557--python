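"""Kinetic transition network thermodynamics and kinetics.

A network of local minima connected by transition states, with
potential energies in kcal/mol, supports equilibrium occupation
probabilities (harmonic superposition when vibrational data are
available, plain Boltzmann weighting otherwise), basin content under an
energy cutoff, Arrhenius/harmonic-TST rates per transition state, and
two-state inter-funnel rates extracted either from the full
master-equation spectrum or by graph-transformation elimination of the
intervening minima.  All Boltzmann work is done in the log domain so
that free-energy gaps of tens of kcal/mol do not underflow.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.special import logsumexp

from .classify import EnsembleComposition

#: Boltzmann constant in kcal/(mol K)
KB = 0.0019872


class NetworkError(ValueError):
    pass


@dataclass
class Minimum:
    id: int
    energy: float
    log_prod_freq: float | None = None
    symmetry: int = 1
    family: str | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.energy):
            raise NetworkError(f"minimum {self.id}: energy not finite")
        if self.symmetry < 1:
            raise NetworkError(f"minimum {self.id}: symmetry must be >= 1")


@dataclass
class TransitionStateRec:
    id: int
    energy: float
    min1: int
    min2: int
    log_prod_freq: float | None = None
    symmetry: int = 1

    def __post_init__(self) -> None:
        if not math.isfinite(self.energy):
            raise NetworkError(f"ts {self.id}: energy not finite")
        if self.min1 == self.min2:
            raise NetworkError(f"ts {self.id}: min1 == min2")


@dataclass
class TransitionNetwork:
    minima: dict[int, Minimum]
    transition_states: list[TransitionStateRec]

    def __post_init__(self) -> None:
        if not self.minima:
            raise NetworkError("network has no minima")
        for ts in self.transition_states:
            for m in (ts.min1, ts.min2):
                if m not in self.minima:
                    raise NetworkError(f"ts {ts.id} references missing minimum {m}")
            floor = max(self.minima[ts.min1].energy, self.minima[ts.min2].energy)
            if ts.energy < floor:
                warnings.warn(
                    f"ts {ts.id}: energy {ts.energy} below its minima ({floor})",
                    stacklevel=2)

    @property
    def ids(self) -> list[int]:
        return sorted(self.minima)

    def edges(self) -> Iterable[tuple[int, int, float]]:
        for ts in self.transition_states:
            yield ts.min1, ts.min2, ts.energy


@dataclass(frozen=True)
class RateParams:
    temperature: float = 298.0  # K
    prefactor: float = 1e13     # s^-1, used when no frequency data

    def __post_init__(self) -> None:
        if self.temperature <= 0 or self.prefactor <= 0:
            raise ValueError("temperature and prefactor must be positive")

    @property
    def kt(self) -> float:
        return KB * self.temperature


# ---------------------------------------------------------------------------
# plain-text min/ts tables
# ---------------------------------------------------------------------------
# full dialect:    min "energy logfreq sym ix iy iz" / ts "energy logfreq sym min1 min2"
# minimal dialect: min "energy"                      / ts "energy min1 min2"

def _read_rows(table) -> list[tuple[int, list[str]]]:
    if hasattr(table, "read"):
        text = table.read()
    elif isinstance(table, (str, Path)) and "\n" not in str(table):
        text = Path(table).read_text()
    else:
        text = str(table)
    rows = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        fields = line.split()
        if fields:
            rows.append((lineno, fields))
    return rows


def _parse_float(value: str, lineno: int, what: str) -> float:
    try:
        return float(value)
    except ValueError:
        raise NetworkError(f"line {lineno}: non-numeric {what}: {value!r}") from None


def load_network(min_table, ts_table, dialect: str = "auto") -> TransitionNetwork:
    """Load a network from whitespace-separated minima/TS tables.

    Ids are assigned by line order starting at 1, mirroring the usual
    stationary-point database convention.
    """
    min_rows = _read_rows(min_table)
    ts_rows = _read_rows(ts_table)
    if not min_rows:
        raise NetworkError("empty minima table")
    if dialect == "auto":
        dialect = "full" if len(min_rows[0][1]) >= 3 else "minimal"
    if dialect not in ("full", "minimal"):
        raise ValueError(f"unknown dialect {dialect!r}")

    minima: dict[int, Minimum] = {}
    for mid, (lineno, fields) in enumerate(min_rows, start=1):
        energy = _parse_float(fields[0], lineno, "energy")
        if dialect == "full":
            if len(fields) < 3:
                raise NetworkError(f"line {lineno}: full dialect needs >= 3 fields")
            logf = _parse_float(fields[1], lineno, "log product frequency")
            sym = int(_parse_float(fields[2], lineno, "symmetry"))
            minima[mid] = Minimum(mid, energy, logf, sym)
        else:
            minima[mid] = Minimum(mid, energy)

    tss: list[TransitionStateRec] = []
    for tid, (lineno, fields) in enumerate(ts_rows, start=1):
        energy = _parse_float(fields[0], lineno, "energy")
        if dialect == "full":
            if len(fields) < 5:
                raise NetworkError(f"line {lineno}: full dialect needs >= 5 fields")
            logf = _parse_float(fields[1], lineno, "log product frequency")
            sym = int(_parse_float(fields[2], lineno, "symmetry"))
            m1 = int(_parse_float(fields[3], lineno, "min1"))
            m2 = int(_parse_float(fields[4], lineno, "min2"))
            ts = TransitionStateRec(tid, energy, m1, m2, logf, sym)
        else:
            if len(fields) < 3:
                raise NetworkError(f"line {lineno}: minimal dialect needs 3 fields")
            m1 = int(_parse_float(fields[1], lineno, "min1"))
            m2 = int(_parse_float(fields[2], lineno, "min2"))
            ts = TransitionStateRec(tid, energy, m1, m2)
        for m in (ts.min1, ts.min2):
            if m not in minima:
                raise NetworkError(f"line {lineno}: ts references missing minimum {m}")
        tss.append(ts)
    return TransitionNetwork(minima, tss)


def save_network(net: TransitionNetwork, min_sink, ts_sink,
                 dialect: str = "minimal") -> None:
    def _write(sink, lines: list[str]) -> None:
        text = "\n".join(lines) + "\n"
        if hasattr(sink, "write"):
            sink.write(text)
        else:
            Path(sink).write_text(text)

    min_lines, ts_lines = [], []
    for mid in net.ids:
        m = net.minima[mid]
        if dialect == "full":
            min_lines.append(f"{m.energy!r} {(m.log_prod_freq or 0.0)!r} {m.symmetry} 0 0 0")
        else:
            min_lines.append(f"{m.energy!r}")
    for ts in net.transition_states:
        if dialect == "full":
            ts_lines.append(
                f"{ts.energy!r} {(ts.log_prod_freq or 0.0)!r} {ts.symmetry} {ts.min1} {ts.min2}")
        else:
            ts_lines.append(f"{ts.energy!r} {ts.min1} {ts.min2}")
    _write(min_sink, min_lines)
    _write(ts_sink, ts_lines)


# ---------------------------------------------------------------------------
# thermodynamics
# ---------------------------------------------------------------------------

def _log_weights(net: TransitionNetwork, params: RateParams) -> np.ndarray:
    """Unnormalized log equilibrium weights per minimum (sorted by id)."""
    ids = net.ids
    have_freq = [net.minima[i].log_prod_freq is not None for i in ids]
    if any(have_freq) and not all(have_freq):
        raise NetworkError("frequency data must be present for all minima or none")
    logw = np.array([-net.minima[i].energy / params.kt for i in ids])
    if all(have_freq):
        logw -= np.array([net.minima[i].log_prod_freq for i in ids])
        logw -= np.log([net.minima[i].symmetry for i in ids])
    return logw


def occupation(net: TransitionNetwork, params: RateParams = RateParams()
               ) -> dict[int, float]:
    """Equilibrium occupation probability per minimum (sums to 1)."""
    ids = net.ids
    logw = _log_weights(net, params)
    logz = logsumexp(logw)
    return {i: float(np.exp(lw - logz)) for i, lw in zip(ids, logw)}


@dataclass
class BasinContent:
    subset: list[int]
    uniform: EnsembleComposition
    boltzmann: EnsembleComposition


def basin_subset(net: TransitionNetwork, bottom: int, cutoff: float) -> list[int]:
    """Minima connected to ``bottom`` below an energy threshold.

    The threshold is E(bottom) + cutoff; connectivity uses only
    transition states at or below the threshold, restricted to minima at
    or below the threshold.
    """
    if bottom not in net.minima:
        raise NetworkError(f"unknown bottom minimum {bottom}")
    threshold = net.minima[bottom].energy + cutoff
    allowed = {i for i in net.ids if net.minima[i].energy <= threshold}
    adj: dict[int, set[int]] = {i: set() for i in allowed}
    for m1, m2, e in net.edges():
        if e <= threshold and m1 in allowed and m2 in allowed:
            adj[m1].add(m2)
            adj[m2].add(m1)
    seen = {bottom}
    stack = [bottom]
    while stack:
        cur = stack.pop()
        for nxt in adj[cur]:
            if nxt not in seen:
                seen.add(nxt)
                stack.append(nxt)
    return sorted(seen)


def basin_content(net: TransitionNetwork, bottom: int, cutoff: float,
                  labels: Mapping[int, str] | None = None,
                  params: RateParams = RateParams()) -> BasinContent:
    """Family composition of the basin reachable from ``bottom``.

    Every minimum in the subset must carry a family label (either via
    ``labels`` or the minimum's own ``family`` field).  Both uniform and
    Boltzmann-weighted compositions are returned, since published basin
    percentages do not state the weighting.
    """
    subset = basin_subset(net, bottom, cutoff)

    def label(i: int) -> str:
        lab = (labels or {}).get(i, net.minima[i].family)
        if lab is None:
            raise NetworkError(f"minimum {i} in basin subset has no family label")
        return lab

    labs = [label(i) for i in subset]
    families = sorted(set(labs))
    n = len(subset)
    uniform = {f: labs.count(f) / n for f in families}

    ids = net.ids
    logw_all = dict(zip(ids, _log_weights(net, params)))
    logw = np.array([logw_all[i] for i in subset])
    p = np.exp(logw - logsumexp(logw))
    boltz = {f: float(p[[lab == f for lab in labs]].sum()) for f in families}
    boltz = {f: v / sum(boltz.values()) for f, v in boltz.items()}
    return BasinContent(
        subset,
        EnsembleComposition(uniform, n, "uniform"),
        EnsembleComposition(boltz, n, "boltzmann"),
    )


# ---------------------------------------------------------------------------
# kinetics
# ---------------------------------------------------------------------------

def ts_rate(net: TransitionNetwork, ts: TransitionStateRec,
            direction: str = "forward",
            params: RateParams = RateParams()) -> float:
    """Rate over one transition state in s^-1.

    ``direction`` 'forward' is min1 -> min2, 'backward' the reverse.
    Without frequency data: k = prefactor * exp(-dE / kT).  With
    frequency data the prefactor is the harmonic-TST frequency ratio
    exp(log_prod_freq(source) - log_prod_freq(ts)) * (o_source / o_ts).
    Negative barriers are clamped to zero with a warning.
    """
    if direction not in ("forward", "backward"):
        raise ValueError("direction must be 'forward' or 'backward'")
    source = net.minima[ts.min1 if direction == "forward" else ts.min2]
    barrier = ts.energy - source.energy
    if barrier < 0:
        warnings.warn(f"ts {ts.id}: negative barrier {barrier:.3f} clamped to 0",
                      stacklevel=2)
        barrier = 0.0
    if source.log_prod_freq is not None and ts.log_prod_freq is not None:
        log_pref = (source.log_prod_freq - ts.log_prod_freq
                    + math.log(source.symmetry / ts.symmetry))
        return float(math.exp(log_pref - barrier / params.kt))
    return float(params.prefactor * math.exp(-barrier / params.kt))


def rate_matrix(net: TransitionNetwork, params: RateParams = RateParams()
                ) -> tuple[np.ndarray, list[int]]:
    """Master-equation generator K (columns sum to zero) over all minima."""
    ids = net.ids
    index = {i: k for k, i in enumerate(ids)}
    n = len(ids)
    K = np.zeros((n, n))
    for ts in net.transition_states:
        i, j = index[ts.min1], index[ts.min2]
        K[j, i] += ts_rate(net, ts, "forward", params)
        K[i, j] += ts_rate(net, ts, "backward", params)
    np.fill_diagonal(K, K.diagonal() - K.sum(axis=0))
    return K, ids


def _two_state_split(net: TransitionNetwork, set_a: Sequence[int],
                     set_b: Sequence[int], lam: float,
                     params: RateParams) -> tuple[float, float]:
    ids = net.ids
    logw = dict(zip(ids, _log_weights(net, params)))
    la = logsumexp([logw[i] for i in set_a])
    lb = logsumexp([logw[i] for i in set_b])
    lz = logsumexp([la, lb])
    pa, pb = math.exp(la - lz), math.exp(lb - lz)
    return lam * pb, lam * pa


def _check_sets(net: TransitionNetwork, set_a, set_b) -> tuple[list[int], list[int]]:
    sa, sb = sorted(set(set_a)), sorted(set(set_b))
    if not sa or not sb:
        raise NetworkError("sets must be non-empty")
    if set(sa) & set(sb):
        raise NetworkError("sets must be disjoint")
    for i in sa + sb:
        if i not in net.minima:
            raise NetworkError(f"unknown minimum {i}")
    return sa, sb


def _symmetrized_slowest_eigenvalue(K: np.ndarray, pi: np.ndarray) -> float:
    """Slowest nonzero relaxation rate of a detailed-balance generator."""
    s = np.sqrt(pi)
    S = (K * s[np.newaxis, :]) / s[:, np.newaxis]
    S = 0.5 * (S + S.T)
    evals = np.linalg.eigvalsh(S)
    rates = -evals
    rates.sort()  # ascending; rates[0] ~ 0 (equilibrium mode)
    if len(rates) < 2:
        raise NetworkError("network too small for a relaxation eigenvalue")
    return float(rates[1])


def interfunnel_rate(net: TransitionNetwork, set_a: Sequence[int],
                     set_b: Sequence[int],
                     params: RateParams = RateParams(),
                     method: str = "master") -> tuple[float, float]:
    """Two-state rates (k_ab, k_ba) between two groups of minima.

    'master' computes the slowest nonzero relaxation eigenvalue of the
    full master-equation generator and splits it by the equilibrium
    populations of the two sets (restricted to their union).  'gt'
    eliminates the intervening minima by shift-aware graph
    transformation (Schur complement with self-consistent eigenvalue
    shift) and extracts the same eigenvalue from the reduced network;
    both satisfy detailed balance k_ab / k_ba = P_b / P_a exactly.
    """
    sa, sb = _check_sets(net, set_a, set_b)
    K, ids = rate_matrix(net, params)
    index = {i: k for k, i in enumerate(ids)}
    occ = occupation(net, params)
    pi = np.array([occ[i] for i in ids])

    s_idx = [index[i] for i in sa + sb]
    t_idx = [k for k in range(len(ids)) if k not in set(s_idx)]

    # connectivity check between the two sets
    import networkx as nx
    g = nx.Graph()
    g.add_nodes_from(ids)
    g.add_edges_from((m1, m2) for m1, m2, _ in net.edges())
    if not any(nx.has_path(g, a, b) for a in sa for b in sb):
        raise NetworkError("no path connects the two sets")

    if method == "master":
        lam = _symmetrized_slowest_eigenvalue(K, pi)
    elif method == "gt":
        Kss = K[np.ix_(s_idx, s_idx)]
        pis = pi[s_idx]
        if not t_idx:
            lam = _symmetrized_slowest_eigenvalue(Kss, pis / pis.sum())
        else:
            Kst = K[np.ix_(s_idx, t_idx)]
            Kts = K[np.ix_(t_idx, s_idx)]
            Ktt = K[np.ix_(t_idx, t_idx)]
            # A relaxation rate lam of the full generator is a fixed point of
            # lam = eig(Kss - Kst (Ktt + lam I)^-1 Kts): eliminating the
            # intervening minima with an eigenvalue shift is exact, not an
            # approximation.  Start from the censored (unshifted) network.
            lam = 0.0
            eye = np.eye(len(t_idx))
            for it in range(200):
                reduced = Kss - Kst @ np.linalg.solve(Ktt + lam * eye, Kts)
                rates = np.sort(np.real(-np.linalg.eigvals(reduced)))
                if it == 0:
                    new_lam = float(rates[1]) if len(rates) > 1 else float(rates[0])
                else:
                    new_lam = float(rates[np.argmin(np.abs(rates - lam))])
                if abs(new_lam - lam) <= 1e-13 * max(abs(new_lam), 1e-300):
                    lam = new_lam
                    break
                lam = new_lam
            else:
                raise NetworkError("graph-transformation eigenvalue did not converge")
    else:
        raise ValueError(f"unknown method {method!r}")
    return _two_state_split(net, sa, sb, lam, params)


def free_energy_gap(net: TransitionNetwork, set_a: Sequence[int],
                    set_b: Sequence[int],
                    params: RateParams = RateParams()) -> float:
    """Free-energy difference F_a - F_b in kcal/mol (negative: a more stable).

    Computed as -kT ln(P_a / P_b) with equilibrium probabilities
    restricted and renormalized to the union of the two sets, entirely
    in the log domain.
    """
    sa, sb = _check_sets(net, set_a, set_b)
    ids = net.ids
    logw = dict(zip(ids, _log_weights(net, params)))
    la = logsumexp([logw[i] for i in sa])
    lb = logsumexp([logw[i] for i in sb])
    if not (math.isfinite(la) and math.isfinite(lb)):
        raise NetworkError("zero-probability set: review energies in log domain")
    return float(-params.kt * (la - lb))
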