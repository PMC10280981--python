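"""End-to-end orchestration: synthesize or ingest a cohort, score it,
normalize WMH volumes, run the published-frequency comparisons, the
consensus elastic net per subsyndrome, and the PLS correlation, writing
delimited-text outputs plus a JSON manifest.

Stage seeds derive deterministically from the master seed and the stage
name (SHA-256 based), so adding or removing stages never perturbs the
randomness of the others.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import comparisons
from .cohort import CohortSpec, generate_cohort, read_cohort, write_cohort
from .enet import ConsensusElasticNet, EnetConfig
from .npiq import SUBSYNDROME_ITEMS, score_cohort
from .plsc import PLSCorrelation, stable_contributors
from .wmh import normalize_cohort

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "stage_seed",
           "STAGE_ORDER"]

logger = logging.getLogger("npsmap")

STAGE_ORDER = ["synth", "ingest", "score", "normalize", "compare",
               "enet", "plsc"]
#: stages that operate on a cohort table and their in-run prerequisites
_COHORT_STAGES = ("score", "normalize", "enet", "plsc")
_STAGE_NEEDS = {
    "enet": ("score", "normalize"),
    "plsc": ("score", "normalize"),
}


class PipelineError(ValueError):
    pass


def stage_seed(master_seed: int, stage: str, index: int = 0) -> int:
    """Deterministic sub-2^31 seed for a stage derived from the master
    seed, the stage name, and an optional repeat index."""
    digest = hashlib.sha256(
        f"{master_seed}:{stage}:{index}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


@dataclass
class RunConfig:
    """Configuration of a pipeline run."""

    stages: list = field(default_factory=lambda: [
        "synth", "score", "normalize", "compare", "enet", "plsc"])
    input_path: str | None = None
    cohort_spec: dict = field(default_factory=dict)
    enet: dict = field(default_factory=dict)
    plsc: dict = field(default_factory=lambda: {
        "n_perm": 5000, "n_boot": 1000, "bsr_threshold": 2.0})
    out_dir: str = "npsmap_out"
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        unknown = [s for s in self.stages if s not in STAGE_ORDER]
        if unknown:
            raise PipelineError(f"unknown stages: {unknown}")
        if "synth" in self.stages and "ingest" in self.stages:
            raise PipelineError("choose either synth or ingest, not both")
        order = {s: i for i, s in enumerate(STAGE_ORDER)}
        idx = [order[s] for s in self.stages]
        if idx != sorted(idx):
            raise PipelineError(
                f"stages must follow the fixed order {STAGE_ORDER}")
        done = set(self.stages)
        has_source = bool({"synth", "ingest"} & done) or bool(self.input_path)
        for stage in self.stages:
            if stage in _COHORT_STAGES and not has_source:
                raise PipelineError(
                    f"stage {stage!r} needs a cohort (synth/ingest stage "
                    "or input_path)")
            missing = [n for n in _STAGE_NEEDS.get(stage, ())
                       if n not in done]
            if missing:
                raise PipelineError(
                    f"stage {stage!r} requires stage(s) {missing} in this run")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _config_hash(cfg: RunConfig) -> str:
    # out_dir and log level do not affect results, so two runs writing to
    # different places still share a config hash
    d = {k: v for k, v in cfg.to_dict().items()
         if k not in ("out_dir", "log_level")}
    blob = json.dumps(d, sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the requested stages; returns the manifest dict (also written
    to ``<out_dir>/manifest.json``)."""
    cfg.validate()
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), 20))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": cfg.seed, "config_hash": _config_hash(cfg),
        "stages": list(cfg.stages), "stage_seeds": {}, "timings_s": {},
        "row_counts": {}, "outputs": [],
    }

    def _record(name: str, t0: float) -> None:
        manifest["timings_s"][name] = round(time.perf_counter() - t0, 4)

    cohort: pd.DataFrame | None = None
    if "synth" in cfg.stages:
        t0 = time.perf_counter()
        seed = stage_seed(cfg.seed, "synth")
        spec_dict = dict(cfg.cohort_spec)
        spec_dict["seed"] = seed
        spec = CohortSpec.from_dict(spec_dict)
        cohort = generate_cohort(spec)
        manifest["stage_seeds"]["synth"] = seed
        write_cohort(cohort, out / "cohort.tsv")
        manifest["outputs"].append("cohort.tsv")
        _record("synth", t0)
    elif "ingest" in cfg.stages or cfg.input_path:
        t0 = time.perf_counter()
        if not cfg.input_path:
            raise PipelineError("ingest stage requires input_path")
        cohort = read_cohort(cfg.input_path)
        _record("ingest", t0)
    if cohort is not None:
        manifest["row_counts"]["cohort"] = int(len(cohort))

    if "score" in cfg.stages:
        t0 = time.perf_counter()
        cohort = score_cohort(cohort)
        _record("score", t0)
    if "normalize" in cfg.stages:
        t0 = time.perf_counter()
        cohort = normalize_cohort(cohort)
        write_cohort(cohort, out / "cohort_scored.tsv")
        manifest["outputs"].append("cohort_scored.tsv")
        _record("normalize", t0)

    if "compare" in cfg.stages:
        t0 = time.perf_counter()
        freq = comparisons.frequency_chi2_report()
        pair = comparisons.pairwise_fisher_report()
        freq.to_csv(out / "comparisons_frequency.tsv", sep="\t", index=False)
        pair.to_csv(out / "comparisons_pairwise.tsv", sep="\t", index=False)
        manifest["outputs"] += ["comparisons_frequency.tsv",
                                "comparisons_pairwise.tsv"]
        _record("compare", t0)

    design_ns = []
    if "enet" in cfg.stages:
        t0 = time.perf_counter()
        enet_cfg = EnetConfig(**cfg.enet)
        for i, sub in enumerate(SUBSYNDROME_ITEMS):
            seed = stage_seed(cfg.seed, "enet", i)
            model = ConsensusElasticNet.from_cohort(cohort, sub, enet_cfg)
            design_ns.append(model.design.n)
            res = model.fit(seed=seed)
            res.coef_table.to_csv(out / f"enet_{sub}.tsv", sep="\t")
            manifest["outputs"].append(f"enet_{sub}.tsv")
            manifest["stage_seeds"][f"enet:{sub}"] = seed
        _record("enet", t0)

    if "plsc" in cfg.stages:
        t0 = time.perf_counter()
        seed = stage_seed(cfg.seed, "plsc")
        manifest["stage_seeds"]["plsc"] = seed
        model = PLSCorrelation.from_cohort(cohort)
        design_ns.append(len(model.X))
        res = model.fit()
        res.permutation_test(n_perm=int(cfg.plsc.get("n_perm", 5000)),
                             seed=seed)
        boot = res.bootstrap_ratios(
            n_boot=int(cfg.plsc.get("n_boot", 1000)), seed=seed + 1,
            threshold=float(cfg.plsc.get("bsr_threshold", 2.0)))
        res.component_table().to_csv(out / "plsc_components.tsv", sep="\t",
                                     index=False)
        boot.bsr_y.to_csv(out / "plsc_bsr_outcomes.tsv", sep="\t")
        boot.bsr_x.to_csv(out / "plsc_bsr_predictors.tsv", sep="\t")
        dx_labels = model.strata.str.split(":").str[-1]
        res.score_table(labels=dx_labels).to_csv(
            out / "plsc_scores.tsv", sep="\t", index=False)
        stable = stable_contributors(boot, 0,
                                     float(cfg.plsc.get("bsr_threshold", 2.0)))
        (out / "plsc_stable_predictors.txt").write_text(
            "\n".join(stable) + "\n")
        manifest["outputs"] += ["plsc_components.tsv", "plsc_bsr_outcomes.tsv",
                                "plsc_bsr_predictors.tsv", "plsc_scores.tsv",
                                "plsc_stable_predictors.txt"]
        _record("plsc", t0)

    if design_ns:
        if len(set(design_ns)) != 1:
            logger.warning("design matrices differ in complete-case n: %s",
                           design_ns)
        manifest["row_counts"]["modelling_n"] = int(design_ns[0])

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
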