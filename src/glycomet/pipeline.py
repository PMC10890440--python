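"""End-to-end orchestration: simulate/load -> preprocess -> scans ->
group networks + MDC -> (optional) pathway enrichment, with a JSON run
manifest recording inputs, seeds, dimensions, warnings, significant-hit
counts and output checksums. Reruns with the same config and seed are
bit-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import CONTRAST_NAMES, ScanSpec, run_scan
from .containers import GROUPS, MetaboliteMatrix, read_cohort, write_cohort
from .enrichment import load_pathway_db, run_enrichment
from .network import ModuleDetector, NetworkConfig, choose_soft_power, mdc_permutation_test
from .preprocess import (build_change_table, covariate_frame, impute_half_min,
                         presence_filter, residualize, sum_normalize)
from .simulate import PlantedEffect, PlantedModule, SynthConfig, generate_cohort

#: MDC comparisons are run for these ordered group pairs (A vs B, testing
#: the modules detected in A).
MDC_PAIRS = (("RYGB", "IMI"), ("RYGB", "BAND"), ("BAND", "IMI"))

DEFAULT_SCANS = (
    ScanSpec(outcome="fpg", exposure="baseline"),
    ScanSpec(outcome="hba1c", exposure="baseline"),
    ScanSpec(outcome="fpg", exposure="change"),
    ScanSpec(outcome="hba1c", exposure="change"),
)


@dataclass
class PipelineConfig:
    synth: SynthConfig = field(default_factory=SynthConfig)
    cohort_path: str | None = None          # load instead of simulating
    matrix_path: str | None = None
    annotations_path: str | None = None
    scans: tuple[ScanSpec, ...] = DEFAULT_SCANS
    network: NetworkConfig = field(default_factory=NetworkConfig)
    gmt_path: str | None = None
    edges_path: str | None = None
    presence_threshold: float = 0.5
    alpha: float = 0.05
    q_threshold: float = 0.05
    out_dir: str = "glycomet_out"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1 and 0 <= self.q_threshold < 1):
            raise ValueError("alpha must be in (0,1), q_threshold in [0,1)")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "synth" in d:
            s = dict(d["synth"])
            if "modules" in s:
                s["modules"] = [PlantedModule(tuple(m["member_ids"]), m["rho_by_group"])
                                for m in s["modules"]]
            if "effects" in s:
                s["effects"] = [PlantedEffect(**e) for e in s["effects"]]
            d["synth"] = SynthConfig(**s)
        if "scans" in d:
            d["scans"] = tuple(ScanSpec(**sc) for sc in d["scans"])
        if "network" in d:
            d["network"] = NetworkConfig(**d["network"])
        return cls(**d)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", float_format="%.6g")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": {},
        "warnings": [],
        "files": {},
    }
    caught: list[str] = []

    def stage(name):
        def wrap(fn):
            try:
                with warnings.catch_warnings(record=True) as wlist:
                    warnings.simplefilter("always")
                    result = fn()
                for w in wlist:
                    caught.append(f"{name}: {w.message}")
                return result
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return wrap

    # --- stage: input ------------------------------------------------------
    @stage("input")
    def _input():
        if config.cohort_path and config.matrix_path and config.annotations_path:
            cohort = read_cohort(config.cohort_path)
            matrix = MetaboliteMatrix.read(config.matrix_path, config.annotations_path)
            truth = None
            source = "loaded"
        else:
            synth = dataclasses.replace(config.synth, seed=config.seed)
            cohort, matrix, truth = generate_cohort(synth)
            source = "simulated"
        return cohort, matrix, truth, source

    cohort, matrix, truth, source = _input
    write_cohort(cohort, out / "cohort.csv")
    paths = matrix.write(out)
    if truth is not None:
        truth.to_json(out / "ground_truth.json")
    manifest["stages"]["input"] = {
        "source": source, "n_participants": len(cohort),
        "n_samples": matrix.n_samples, "n_metabolites": matrix.n_metabolites,
        "n_known": int(matrix.feature_meta["known"].sum()),
    }

    # --- stage: preprocess -------------------------------------------------
    @stage("preprocess")
    def _prep():
        norm = sum_normalize(matrix)
        filtered = presence_filter(norm, config.presence_threshold)
        return impute_half_min(filtered)

    prepped = _prep
    change = build_change_table(prepped, cohort)
    _write_tsv(change, out / "change_table.tsv")
    manifest["stages"]["preprocess"] = {
        "presence_threshold": config.presence_threshold,
        "n_metabolites_retained": prepped.n_metabolites,
        "n_metabolites_dropped": matrix.n_metabolites - prepped.n_metabolites,
        "weight_loss_convention": "(follow-up - baseline) / baseline (fraction)",
        "standardization": "exposures standardized after percent change",
    }

    # --- stage: scans ------------------------------------------------------
    scan_info = {}
    for spec in config.scans:
        @stage(f"scan:{spec.name}")
        def _scan(spec=spec):
            return run_scan(cohort, prepped, spec)
        table = _scan
        _write_tsv(table, out / f"scan_{spec.name}.tsv")
        sig = {
            c: int((table[f"q_{c.lower()}"] < config.q_threshold).sum())
            for c in CONTRAST_NAMES
        }
        scan_info[spec.name] = {
            "n_metabolites": len(table),
            "n_failed": int((table["error"] != "").sum()),
            "significant_at_q": sig,
        }
    manifest["stages"]["scans"] = scan_info

    # --- stage: networks ---------------------------------------------------
    @stage("network")
    def _network():
        values = prepped.values
        z = (values - values.mean()) / values.std(ddof=1)
        cov = covariate_frame(cohort)
        sample_cov = cov.loc[prepped.sample_meta["participant_id"]].set_axis(z.index)
        resid = residualize(z, sample_cov)
        if config.network.soft_power == "auto":
            power = choose_soft_power(resid, target=config.network.scale_free_r2_target)
        else:
            power = int(config.network.soft_power)
        detectors = {}
        for g in GROUPS:
            Xg = resid.loc[prepped.sample_meta["group"] == g]
            det = ModuleDetector(
                soft_power=power,
                tree_cut_height=config.network.tree_cut_height,
                min_module_size=config.network.min_module_size,
            ).fit(Xg)
            detectors[g] = (det, Xg)
        return power, detectors

    power, detectors = _network
    module_info = {}
    for g, (det, Xg) in detectors.items():
        rows = []
        for met in det.assignment_.index:
            color = det.assignment_.loc[met]
            conn = float(det.adjacency_.loc[met, det.modules_[color]].sum() - 1.0) \
                if color != "grey" else 0.0
            rows.append({
                "module": color,
                "intramodular_connectivity": conn,
                "hub": det.hubs_.get(color) == met,
            })
        _write_tsv(pd.DataFrame(rows, index=det.assignment_.index)
                   .rename_axis("metabolite"), out / f"modules_{g}.tsv")
        module_info[g] = {
            "n_modules": len(det.modules_),
            "module_sizes": {c: int(len(m)) for c, m in det.modules_.items()},
            "hubs": det.hubs_,
        }
    manifest["stages"]["network"] = {"soft_power": power, "groups": module_info}

    # --- stage: MDC --------------------------------------------------------
    @stage("mdc")
    def _mdc():
        # spawn_key distinct from the simulator's children of the same seed
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(97,)))
        rows = []
        for a, b in MDC_PAIRS:
            det_a, X_a = detectors[a]
            _, X_b = detectors[b]
            for color, members in det_a.modules_.items():
                res = mdc_permutation_test(
                    X_a, X_b, members, power,
                    n_perm=config.network.n_perm, alpha=config.alpha,
                    rng=rng, module=color, group_a=a, group_b=b)
                rows.append({
                    "module": color, "group_a": a, "group_b": b,
                    "n_members": len(members), "statistic": res.statistic,
                    "connectivity_ratio": res.ratio, "perm_p": res.perm_p,
                    "call": res.call,
                })
        return rows

    mdc_rows = _mdc
    mdc_table = pd.DataFrame(
        mdc_rows, columns=["module", "group_a", "group_b", "n_members",
                           "statistic", "connectivity_ratio", "perm_p", "call"])
    _write_tsv(mdc_table.set_index("module"), out / "mdc.tsv")
    manifest["stages"]["mdc"] = {
        "n_pairs": len(MDC_PAIRS),
        "pairs": [f"{a}_vs_{b}" for a, b in MDC_PAIRS],
        "n_perm": config.network.n_perm,
        "calls": {f"{r['group_a']}_vs_{r['group_b']}:{r['module']}": r["call"]
                  for r in mdc_rows},
    }

    # --- stage: enrichment (optional) --------------------------------------
    if config.gmt_path:
        @stage("enrichment")
        def _enrich():
            db = load_pathway_db(config.gmt_path, config.edges_path)
            known = set(prepped.known_ids)
            sig_members: set[str] = set()
            for r in mdc_rows:
                if r["call"] != "none":
                    det_a, _ = detectors[r["group_a"]]
                    sig_members |= set(det_a.modules_[r["module"]]) & known
            background = [str(k) for k in prepped.known_ids]
            return run_enrichment(sorted(sig_members), db, background)
        table, unmatched = _enrich
        _write_tsv(table.set_index("pathway"), out / "enrichment.tsv")
        manifest["stages"]["enrichment"] = {
            "n_pathways": len(table), "n_hits_unmatched": len(unmatched),
            "unmatched": unmatched,
        }

    manifest["warnings"] = caught
    for p in sorted(out.iterdir()):
        if p.is_file() and p.name != "manifest.json":
            manifest["files"][p.name] = _sha256(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
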