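"""End-to-end reports: ensemble classification, landscape analysis and
peptide-interface profiling, with serializable configuration.

Reports are JSON + TSV; every report embeds the resolved configuration
and the package version so it can be regenerated bit-identically
(modulo the timestamp field) from its inputs.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import classify_ensemble, composition, projection_histogram
from .contacts import HBondCriteria
from .disconnectivity import build_dgraph, funnel_assignment, render_dgraph
from .geometry import AngleSpec
from .io import read_pdb
from .ktn import (RateParams, TransitionNetwork, basin_content, free_energy_gap,
                  interfunnel_rate, load_network, occupation)
from .interface import interface_report
from .structure import Ensemble


@dataclass
class RunConfig:
    """Resolved parameters for a pipeline run; fully serializable."""

    input_path: str | None = None
    min_path: str | None = None
    ts_path: str | None = None
    output_dir: str = "hairpin_report"
    # geometry / classification
    apex_pair: tuple[int, int] = (43, 66)
    distal_pair: tuple[int, int] = (45, 64)
    probe: int = 40
    hbond_d_max: float = 3.5
    hbond_angle_min: float = 120.0
    u63_threshold: float = 100.0
    # ktn
    temperature: float = 298.0
    prefactor: float = 1e13
    basin_cutoff: float = 15.0
    bottoms: tuple[int, ...] = ()
    level_spacing: float = 1.0
    # interface
    peptide_chain: str = "B"
    rna_chain: str = "A"
    grid: float = 0.8
    dielectric: float = 78.5
    seed: int = 0

    def angle_spec(self) -> AngleSpec:
        return AngleSpec(tuple(self.apex_pair), tuple(self.distal_pair),
                         self.probe)

    def criteria(self) -> HBondCriteria:
        return HBondCriteria(self.hbond_d_max, self.hbond_angle_min)

    def rate_params(self) -> RateParams:
        return RateParams(self.temperature, self.prefactor)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        return cls(**{k: tuple(v) if isinstance(v, list) else v
                      for k, v in data.items()})


def _provenance(config: RunConfig) -> dict:
    return {"package": "hairpin7sk", "version": __version__,
            "config": config.to_dict(), "timestamp": time.strftime("%FT%T")}


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=1, default=str) + "\n")


def run_ensemble_report(config: RunConfig, ens: Ensemble | None = None) -> dict:
    """Classify an ensemble and write per-frame TSV, composition JSON,
    projection histogram TSV and a triplet summary."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if ens is None:
        if not config.input_path:
            raise ValueError("no input ensemble")
        ens = read_pdb(config.input_path)
    frames = classify_ensemble(ens, config.angle_spec(), config.criteria())

    rows = []
    for i, f in enumerate(frames):
        flags = f.triplet_flags
        rows.append({"frame": i, "xi_deg": f.xi, "u63_deg": f.u63,
                     "family": f.family,
                     "t1": flags["T1"], "t2": flags["T2"], "t3": flags["T3"],
                     "m2star": flags["M2STAR"]})
    table = pd.DataFrame(rows)
    table.to_csv(out / "frames.tsv", sep="\t", index=False)

    comp = composition(frames)
    counts, xi_edges, u63_edges = projection_histogram(frames)
    hist = pd.DataFrame(counts,
                        index=pd.Index(xi_edges[:-1], name="xi_edge"),
                        columns=u63_edges[:-1])
    hist.to_csv(out / "histogram.tsv", sep="\t")

    report = {
        "n_frames": len(frames),
        "composition": comp.fractions,
        "composition_m2star_folded": comp.folded(),
        "triplet_frame_fractions": {
            t: float(np.mean([f.triplet_flags[t] for f in frames]))
            for t in ("T1", "T2", "T3", "M2STAR")},
        "provenance": _provenance(config),
    }
    _write_json(out / "composition.json", report)
    return report


def run_landscape_report(config: RunConfig,
                         net: TransitionNetwork | None = None,
                         labels: dict[int, str] | None = None) -> dict:
    """Occupations, basin contents, inter-funnel rates, free-energy gaps
    and a disconnectivity SVG for a minima/TS database."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if net is None:
        if not (config.min_path and config.ts_path):
            raise ValueError("no minima/ts tables")
        net = load_network(config.min_path, config.ts_path)
    params = config.rate_params()
    occ = occupation(net, params)
    report: dict = {"n_minima": len(net.minima),
                    "n_ts": len(net.transition_states),
                    "occupation": {str(k): v for k, v in occ.items()}}

    label_map = dict(labels or {})
    for i, m in net.minima.items():
        if i not in label_map and m.family:
            label_map[i] = m.family

    bottoms = list(config.bottoms)
    if not bottoms:
        bottoms = [min(net.ids, key=lambda i: net.minima[i].energy)]
    if len(net.minima) > 1:
        assignment = funnel_assignment(net, bottoms)
        report["funnel_assignment"] = {str(k): v for k, v in assignment.items()}
        report["n_funnels"] = len({v for v in assignment.values()
                                   if v != "unassigned"})
        contents = {}
        for b in bottoms:
            try:
                bc = basin_content(net, b, config.basin_cutoff,
                                   labels=label_map, params=params)
                contents[str(b)] = {
                    "subset_size": len(bc.subset),
                    "uniform": bc.uniform.fractions,
                    "boltzmann": bc.boltzmann.fractions}
            except Exception as exc:  # unlabeled minima: report, don't die
                contents[str(b)] = {"error": str(exc)}
        report["basin_content"] = contents
        if len(bottoms) >= 2:
            rates = {}
            gaps = {}
            sets = {b: [i for i, bb in assignment.items() if bb == b]
                    for b in bottoms}
            for i, a in enumerate(bottoms):
                for b in bottoms[i + 1:]:
                    if a != b and sets[a] and sets[b]:
                        kab, kba = interfunnel_rate(net, sets[a], sets[b],
                                                    params)
                        rates[f"{a}->{b}"] = kab
                        rates[f"{b}->{a}"] = kba
                        gaps[f"F({a})-F({b})"] = free_energy_gap(
                            net, sets[a], sets[b], params)
            report["interfunnel_rates_per_s"] = rates
            report["free_energy_gaps_kcal_mol"] = gaps
    root = build_dgraph(net, config.level_spacing)
    render_dgraph(root, coloring=label_map, sink=out / "dgraph.svg")
    report["provenance"] = _provenance(config)
    _write_json(out / "landscape.json", report)
    return report


def run_interface_report(config: RunConfig, ens: Ensemble | None = None) -> dict:
    """Fingerprints, gap index, Coulomb energy and H-bond persistence for
    an ensemble of peptide-RNA complexes."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if ens is None:
        if not config.input_path:
            raise ValueError("no input ensemble")
        ens = read_pdb(config.input_path)
    rep = interface_report(ens, config.peptide_chain, config.rna_chain,
                           grid=config.grid, dielectric=config.dielectric,
                           criteria=config.criteria())
    rep.fingerprint.to_csv(out / "fingerprint.tsv", sep="\t", index=False)
    rep.hbond_persistence.to_csv(out / "hbond_persistence.tsv", sep="\t",
                                 index=False)
    report = rep.summary()
    report["gap_index_series"] = rep.gap_index_series
    report["coulomb_series"] = rep.coulomb_series
    report["provenance"] = _provenance(config)
    _write_json(out / "interface.json", report)
    return report
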