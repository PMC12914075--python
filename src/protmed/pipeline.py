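"""End-to-end pipeline: features -> selection -> mediation -> trajectories
-> trends -> enrichment, with a manifest and resumable checkpoints.

Every stage reads its inputs from the run directory and writes versioned
text artifacts there, so a failed run can resume: completed stages (same
config hash, artifacts present with matching checksums) are skipped. All
stochastic stages draw their seeds from the single configured seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from protmed import data_model, enrichment, mediation, selection, simulate, trajectories
from protmed.assoc import interaction_model, quartile_table, stratified_effect
from protmed.data_model import TrialSchema, build_feature_matrix, load_trial_table

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """One run: inputs, thresholds and seeds (trial-analysis defaults)."""

    outdir: str = "protmed_run"
    input_csv: str | None = None        # None -> simulate
    gmt: str | None = None
    universe: str = "panel"             # "panel" or a genome background file
    seed: int = 0
    n_subjects: int = 488
    n_proteins: int = 276
    decile_fraction: float = 0.10
    min_models: int = 2
    alpha: float = 0.05
    n_perm: int = 1000
    n_boot: int = 1000
    train_fraction: float = 0.8
    cv_folds: int = 3
    scale: str = "raw"                  # analysis scale for mediation
    learner_grids: dict = field(default_factory=dict)
    echo_slope_predictors: list = field(default_factory=list)  # two proteins

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.as_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class PipelineRun:
    """Sequential stage runner with a checksum manifest."""

    def __init__(self, config: RunConfig):
        self.cfg = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest_path = self.outdir / "manifest.json"
        self.manifest = {"config_hash": config.content_hash(), "stages": {}}
        if self.manifest_path.exists():
            prev = json.loads(self.manifest_path.read_text())
            if prev.get("config_hash") == self.manifest["config_hash"]:
                self.manifest = prev
            else:
                log.info("config changed; ignoring previous checkpoints")
        (self.outdir / "config.yaml").write_text(yaml.safe_dump(config.as_dict()))

    # -- checkpoint machinery ---------------------------------------------
    def _done(self, stage: str) -> bool:
        rec = self.manifest["stages"].get(stage)
        if not rec:
            return False
        for f, digest in rec["files"].items():
            p = self.outdir / f
            if not p.exists() or _sha256(p) != digest:
                return False
        return True

    def _finish(self, stage: str, files: list[Path]) -> None:
        self.manifest["stages"][stage] = {
            "files": {f.name: _sha256(f) for f in files}
        }
        self.manifest_path.write_text(json.dumps(self.manifest, indent=2))

    def _stage(self, name: str, fn) -> None:
        if self._done(name):
            log.info("stage %s: checkpoint hit, skipping", name)
            return
        log.info("stage %s: running", name)
        try:
            files = fn()
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
        self._finish(name, files)

    # -- stages ------------------------------------------------------------
    def run(self) -> Path:
        self._stage("dataset", self.stage_dataset)
        self.dataset = self._load_dataset()
        for visit in self.dataset.schema.follow_ups:
            self._stage(f"select_{visit}", lambda v=visit: self.stage_select(v))
        self._stage("consensus", self.stage_consensus)
        self._stage("screen", self.stage_screen)
        for visit in self.dataset.schema.follow_ups:
            self._stage(f"mediation_{visit}", lambda v=visit: self.stage_mediation(v))
        self._stage("trajectories", self.stage_trajectories)
        self._stage("trends", self.stage_trends)
        if self.cfg.gmt:
            self._stage("enrichment", self.stage_enrichment)
        return self.outdir

    def stage_dataset(self) -> list[Path]:
        out = self.outdir / "data.csv"
        if self.cfg.input_csv:
            schema = self._schema_from_input(self.cfg.input_csv)
            ds = load_trial_table(self.cfg.input_csv, schema)
            ds.to_csv(out)
            (self.outdir / "schema.json").write_text(json.dumps({
                "proteins": list(schema.proteins), "visits": list(schema.visits),
                "visit_times": schema.visit_times, "echo": list(schema.echo),
            }))
            return [out, self.outdir / "schema.json"]
        sim = simulate.SimulationConfig(
            n_subjects=self.cfg.n_subjects, n_proteins=self.cfg.n_proteins,
            seed=self.cfg.seed,
        )
        ds, truth = simulate.simulate_trial(sim)
        ds.to_csv(out)
        (self.outdir / "truth.json").write_text(json.dumps(truth.as_dict(), indent=2))
        (self.outdir / "schema.json").write_text(json.dumps({
            "proteins": list(ds.schema.proteins), "visits": list(ds.schema.visits),
            "visit_times": ds.schema.visit_times, "echo": list(ds.schema.echo),
        }))
        return [out, self.outdir / "truth.json", self.outdir / "schema.json"]

    def _schema_from_input(self, path) -> TrialSchema:
        head = pd.read_csv(path, nrows=0)
        visits = ("baseline", "v1", "v2")
        proteins = sorted({
            c.split("__")[0] for c in head.columns
            if c.split("__")[0].startswith("P") and "__" in c
        })
        return TrialSchema(visits=visits, proteins=tuple(proteins))

    def _load_dataset(self) -> data_model.TrialDataset:
        meta = json.loads((self.outdir / "schema.json").read_text())
        schema = TrialSchema(
            visits=tuple(meta["visits"]),
            visit_times={k: float(v) for k, v in meta["visit_times"].items()},
            proteins=tuple(meta["proteins"]),
            echo=tuple(meta.get("echo", [])),
        )
        return load_trial_table(self.outdir / "data.csv", schema, sep=",")

    def stage_select(self, visit: str) -> list[Path]:
        cfg = self.cfg
        train, test = selection.split_train_test(
            self.dataset, visit, cfg.train_fraction, seed=cfg.seed
        )
        fm = build_feature_matrix(self.dataset, visit, reference_ids=train)
        tr = fm.X.index.intersection(train)
        te = fm.X.index.intersection(test)
        learners = selection.default_learners(cfg.seed)
        for fam, grid in cfg.learner_grids.items():
            learners[fam].grid = grid
        cons, importances, reports = selection.select_features(
            fm.X.loc[tr], fm.y.loc[tr], fm.X.loc[te], fm.y.loc[te],
            learners=learners, n_perm=cfg.n_perm, fraction=cfg.decile_fraction,
            min_models=cfg.min_models, seed=cfg.seed,
        )
        files = []
        for fam, imp in importances.items():
            f = self.outdir / f"importance_{visit}_{fam}.tsv"
            imp.to_csv(f, sep="\t")
            files.append(f)
        f = self.outdir / f"fit_reports_{visit}.json"
        f.write_text(json.dumps({k: dataclasses.asdict(v) for k, v in reports.items()}, indent=2))
        files.append(f)
        f = self.outdir / f"consensus_{visit}.json"
        f.write_text(json.dumps({
            "support": cons.support.to_dict(),
            "members": {k: sorted(v) for k, v in cons.members.items()},
        }, indent=2))
        files.append(f)
        return files

    def stage_consensus(self) -> list[Path]:
        sets = []
        for visit in self.dataset.schema.follow_ups:
            rec = json.loads((self.outdir / f"consensus_{visit}.json").read_text())
            sets.append(selection.ConsensusSet(
                support=pd.Series(rec["support"], dtype=int),
                members={k: set(v) for k, v in rec["members"].items()},
                min_models=self.cfg.min_models,
            ))
        common = selection.cross_timepoint_intersection(*sets[:2])
        f = self.outdir / "consensus_common.json"
        f.write_text(json.dumps({"features": sorted(common.features),
                                 "support": common.support.to_dict()}, indent=2))
        return [f]

    def _candidate_proteins(self) -> list[str]:
        rec = json.loads((self.outdir / "consensus_common.json").read_text())
        prots = {
            f.rsplit("__", 1)[0] for f in rec["features"]
            if f.endswith("__fc") and f.rsplit("__", 1)[0] in self.dataset.schema.proteins
        }
        return sorted(prots)

    def stage_screen(self) -> list[Path]:
        prots = self._candidate_proteins()
        if not prots:
            screen = pd.DataFrame()
        else:
            screen = mediation.screen_candidates(
                self.dataset, prots, alpha=self.cfg.alpha, scale=self.cfg.scale
            )
        f = self.outdir / "screen.tsv"
        screen.to_csv(f, sep="\t")
        return [f]

    def _selected_candidates(self) -> list[str]:
        screen = pd.read_csv(self.outdir / "screen.tsv", sep="\t", index_col=0)
        if screen.empty or "selected" not in screen:
            return []
        return list(screen.index[screen["selected"].fillna(False)])

    def stage_mediation(self, visit: str) -> list[Path]:
        cands = self._selected_candidates()
        files = []
        f = self.outdir / f"mediation_{visit}.json"
        if len(cands) < 2:
            f.write_text(json.dumps({"skipped": "fewer than two candidate mediators"}))
            return [f]
        sig, res = mediation.mediation_analysis(
            self.dataset, cands, visit, scale=self.cfg.scale,
            n_boot=self.cfg.n_boot, seed=self.cfg.seed,
        )
        f.write_text(json.dumps({
            "candidates": cands,
            "weights": sig.weights.to_dict(),
            "result": res.as_dict(),
        }, indent=2))
        files.append(f)
        fc, arm, y, cov = mediation.mediation_inputs(
            self.dataset, cands, visit, scale=self.cfg.scale
        )
        loo = mediation.loo_proportion_loss(
            fc, arm, y, covariates=cov, n_boot=self.cfg.n_boot, seed=self.cfg.seed
        )
        f = self.outdir / f"loo_{visit}.tsv"
        loo.to_csv(f, sep="\t")
        files.append(f)
        return files

    def stage_trajectories(self) -> list[Path]:
        ds = self.dataset
        preds = self.cfg.echo_slope_predictors or self._selected_candidates()[:2]
        files = []
        if len(preds) < 2 or not ds.schema.echo:
            f = self.outdir / "slopes.tsv"
            pd.DataFrame().to_csv(f, sep="\t")
            return [f]
        biomarkers = list(preds[:2]) + list(ds.schema.echo)
        slopes = trajectories.slope_table(ds, biomarkers)
        f = self.outdir / "slopes.tsv"
        slopes.to_csv(f, sep="\t")
        files.append(f)
        cov = pd.DataFrame({
            "age": ds.value("age", ds.schema.baseline),
            "sex": ds.value("sex", ds.schema.baseline),
            "arm": ds.arm.astype(float),
            "egfr": ds.value("egfr", ds.schema.baseline),
        })
        results = {}
        for echo in ds.schema.echo:
            r = trajectories.regress_slopes(
                slopes[echo], slopes[preds[0]], slopes[preds[1]], cov
            )
            results[echo] = {
                "params": r.params.to_dict(), "pvalues": r.pvalues.to_dict(),
                "omnibus_f": r.omnibus_f, "omnibus_p": r.omnibus_p,
                "robust_diverged": r.robust_diverged, "diagnostics": r.diagnostics,
                "n": r.n,
            }
            g = self.outdir / f"surface_{echo}.tsv"
            r.grid.to_csv(g, sep="\t", index=False)
            files.append(g)
        f = self.outdir / "slope_regressions.json"
        f.write_text(json.dumps(results, indent=2))
        files.append(f)
        return files

    def stage_trends(self) -> list[Path]:
        ds = self.dataset
        continuous = [v for v in ("age", "bmi", "sbp", "dbp", "egfr", "picp")
                      if ds.schema.column(v, ds.schema.baseline) in ds.table.columns]
        binary = [v for v in ("sex", "smoker", "diabetes", "cad")
                  if ds.schema.column(v, ds.schema.baseline) in ds.table.columns]
        files = []
        for visit in ds.schema.follow_ups:
            tab = quartile_table(ds, visit, continuous, binary)
            f = self.outdir / f"table1_{visit}.tsv"
            tab.to_csv(f, sep="\t")
            files.append(f)
        cands = self._selected_candidates()
        assoc_out = {}
        if cands:
            top = cands[0]
            visit = ds.schema.follow_ups[-1]
            est, p, _ = interaction_model(ds, top, visit, scale=self.cfg.scale)
            strat = stratified_effect(ds, top, visit, scale=self.cfg.scale)
            assoc_out = {
                "protein": top, "interaction": est, "interaction_p": p,
                "stratified": {
                    "median": strat.median, "below": strat.below,
                    "above": strat.above, "interaction_p": strat.interaction_p,
                },
            }
        f = self.outdir / "assoc.json"
        f.write_text(json.dumps(assoc_out, indent=2))
        files.append(f)
        return files

    def stage_enrichment(self) -> list[Path]:
        ann = enrichment.read_gmt(self.cfg.gmt)
        query = self._candidate_proteins()
        if self.cfg.universe == "panel":
            universe = list(self.dataset.schema.proteins)
        else:
            universe = Path(self.cfg.universe).read_text().split()
        rows = enrichment.ora(query, universe, ann)
        files = []
        f = self.outdir / "ora.tsv"
        rows.to_csv(f, sep="\t")
        files.append(f)
        for mode in ("adjusted", "fold"):
            f = self.outdir / f"ora_{mode}.tsv"
            enrichment.filter_terms(rows, mode).to_csv(f, sep="\t")
            files.append(f)
        return files


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages in order; returns the run directory."""
    return PipelineRun(config).run()
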