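"""End-to-end pipeline: simulate -> metrics -> indices -> cluster -> stats.

Each stage writes CSV tables under an output directory; every CSV
carries a header comment with the config hash and seed, and a JSON run
manifest records inputs, outputs and timestamps.  Re-running with the
same config and seed reproduces byte-identical CSVs (timestamps live
only in the manifest).
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .cluster import (
    FuzzyCMeans,
    cluster_diff_profile,
    cluster_profiles,
    select_c_majority,
    typical_curves,
)
from .covariance import RepeatedMeasuresModel, select_structure_bic
from .daily import correlation_series, onset_detection, per_day_treatment_test
from .errors import GrowthDynError
from .indices import capability_correlations, capability_table
from .io import TraitTable, genotype_means, read_trait_table, wide_matrix
from .metrics import cv_series, decline_table, rgr_series, wue
from .simulate import SimulationConfig, ground_truth, simulate_experiment, water_applied_phase
from .varcomp import variance_components_series

FLOAT_FMT = "%.10g"


@dataclass
class RunManifest:
    version: str
    seed: int
    config_hash: str
    inputs: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    started: float = 0.0
    finished: float = 0.0

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(asdict(self), indent=2) + "\n")


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write_csv(df: pd.DataFrame, path: Path, manifest: RunManifest, index=True) -> None:
    header = f"# growthdyn {manifest.version} config={manifest.config_hash} seed={manifest.seed}\n"
    body = df.to_csv(float_format=FLOAT_FMT, index=index)
    path.write_text(header + body)
    manifest.outputs[path.name] = _digest(path)


DEFAULT_STAGES = (
    "simulate", "metrics", "indices", "cluster", "varcomp",
    "covstruct", "correlate", "onset",
)


def run_pipeline(
    out_dir: str | Path,
    seed: int = 0,
    config: dict | None = None,
    stages: tuple[str, ...] = DEFAULT_STAGES,
    input_csv: str | Path | None = None,
) -> RunManifest:
    """Run the requested stages in dependency order.

    ``config`` is a nested dict with optional per-stage sections
    (``simulate``, ``cluster``, ``covstruct``, ``onset``).  A stage
    failure stops downstream stages with the stage name attached.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config = config or {}
    cfg_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]
    manifest = RunManifest(
        version=__version__, seed=seed, config_hash=cfg_hash, started=time.time()
    )

    sim_cfg = SimulationConfig(seed=seed).replace(**config.get("simulate", {}))
    table: TraitTable | None = None
    if input_csv is not None:
        table = read_trait_table(input_csv)
        manifest.inputs[str(input_csv)] = _digest(Path(input_csv))
    needs_table = set(stages) - {"simulate"}
    if table is None and needs_table and "simulate" not in stages:
        raise GrowthDynError(
            f"stages {sorted(needs_table)} need a trait table: run the "
            "simulate stage or pass input_csv",
            {"missing_stage": "simulate"},
        )

    def stage(name):
        return name in stages

    try:
        if stage("simulate") and table is None:
            table = simulate_experiment(sim_cfg)
            _write_csv(table.data, out / "table.csv", manifest, index=False)
            table.write_schema(out / "schema.json")
            manifest.outputs["schema.json"] = _digest(out / "schema.json")
            _write_csv(ground_truth(sim_cfg), out / "ground_truth.csv", manifest, index=False)

        trait = config.get("trait", "EBv")
        curves = {
            (c.genotype_id, c.treatment): c for c in genotype_means(table, trait)
        }

        if stage("metrics"):
            rgr = pd.DataFrame(
                {f"{g}:{t}": rgr_series(c) for (g, t), c in curves.items()}
            ).T.sort_index()
            _write_csv(rgr, out / "rgr.csv", manifest)
            cv = pd.DataFrame(
                {t: cv_series(table, trait, t) for t in table.treatments}
            )
            _write_csv(cv, out / "cv.csv", manifest)
            wue_rows = []
            for (g, t), c in sorted(curves.items()):
                wue_rows.append(
                    {
                        "genotype": g,
                        "treatment": t,
                        "wue_stress": wue(c, water_applied_phase(sim_cfg, t, 2, 22), "stress"),
                        "wue_recovery": wue(c, water_applied_phase(sim_cfg, t, 22, 35), "recovery"),
                    }
                )
            _write_csv(pd.DataFrame(wue_rows), out / "wue.csv", manifest, index=False)
            _write_csv(decline_table(table, trait), out / "decline.csv", manifest, index=False)

        if stage("indices"):
            for treat in ("W", "NW"):
                if treat not in table.treatments:
                    continue
                water = {
                    "stress": water_applied_phase(sim_cfg, treat, 2, 22),
                    "recovery": water_applied_phase(sim_cfg, treat, 22, 35),
                }
                scores = capability_table(table, treat, trait, water_applied=water)
                _write_csv(scores, out / f"scores_{treat}.csv", manifest)
                r, p = capability_correlations(scores)
                _write_csv(r, out / f"capability_corr_{treat}.csv", manifest)

        if stage("cluster"):
            ccfg = config.get("cluster", {})
            treat = ccfg.get("treatment", "W")
            m = ccfg.get("m", 2.0)
            restarts = ccfg.get("restarts", 20)
            profiles = cluster_profiles(table, trait, treat)
            c_req = ccfg.get("c", "auto")
            if c_req == "auto":
                report = select_c_majority(
                    profiles, m=m, seed=seed, restarts=restarts
                )
                _write_csv(report.table, out / "validity.csv", manifest)
                part = report.partitions[report.selected_c]
            else:
                part = FuzzyCMeans(int(c_req), m=m, seed=seed, restarts=restarts).fit(profiles)
            mem = pd.DataFrame(
                part.membership,
                index=profiles.index,
                columns=[chr(ord("A") + k) for k in range(part.n_clusters)],
            )
            mem["hard"] = [chr(ord("A") + k) for k in part.hard_labels]
            _write_csv(mem, out / "membership.csv", manifest)
            _write_csv(typical_curves(part, profiles), out / "typical_curves.csv", manifest)
            if part.n_clusters == 2:
                _write_csv(
                    cluster_diff_profile(part, profiles).to_frame(),
                    out / "diffprofile.csv", manifest,
                )

        if stage("varcomp"):
            _write_csv(variance_components_series(table, trait), out / "varcomp.csv", manifest)

        if stage("covstruct"):
            vcfg = config.get("covstruct", {})
            thin = int(vcfg.get("thin", 4))
            rows = []
            for treat in table.treatments:
                mat = wide_matrix(genotype_means(table, trait), treat).dropna()
                mat = mat.iloc[:, ::thin]
                model = RepeatedMeasuresModel(mat)
                best, tbl = select_structure_bic(model.fit_all())
                tbl = tbl.reset_index()
                tbl.insert(0, "treatment", treat)
                rows.append(tbl)
            _write_csv(pd.concat(rows, ignore_index=True), out / "covstruct.csv", manifest, index=False)

        if stage("correlate"):
            others = [tr for tr in table.traits if tr != trait]
            frames = []
            for treat in table.treatments:
                for tr in others:
                    cs = correlation_series(table, tr, trait, treat)
                    df = pd.DataFrame(
                        {"r": cs.r, "n": cs.n, "r_crit": cs.critical_value,
                         "significant": cs.significant}
                    )
                    df.insert(0, "trait", tr)
                    df.insert(0, "treatment", treat)
                    frames.append(df.rename_axis("dat").reset_index())
            if frames:
                _write_csv(pd.concat(frames, ignore_index=True), out / "correlations.csv", manifest, index=False)

        if stage("onset"):
            ocfg = config.get("onset", {})
            contrasts = ocfg.get("contrasts", [("W", "C"), ("NW", "C"), ("N", "C")])
            persistence = int(ocfg.get("persistence", 1))
            # one Tukey table per day, shared across all contrasts
            per_day = {}
            for dat in table.grid:
                try:
                    per_day[dat] = per_day_treatment_test(table, trait, dat)
                except GrowthDynError:
                    continue
            rows = []
            for treat, ref in contrasts:
                ps = {}
                for dat, res in per_day.items():
                    for cand in (f"{ref}-{treat}", f"{treat}-{ref}"):
                        if cand in res.index:
                            ps[dat] = res.loc[cand, "p_adj"]
                            break
                if not ps:
                    continue
                rep = onset_detection(
                    pd.Series(ps), persistence=persistence,
                    trait=trait, contrast=f"{treat} vs {ref}",
                )
                rows.append(
                    {
                        "contrast": rep.contrast,
                        "onset_dat": rep.onset_dat,
                        "runs": ";".join(f"{s}-{e}" for s, e in rep.runs),
                        "note": "per-day p-values, no cross-day adjustment",
                    }
                )
            _write_csv(pd.DataFrame(rows), out / "onset.csv", manifest, index=False)
    except GrowthDynError:
        manifest.finished = time.time()
        manifest.write(out / "manifest.json")
        raise

    manifest.finished = time.time()
    manifest.write(out / "manifest.json")
    return manifest
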