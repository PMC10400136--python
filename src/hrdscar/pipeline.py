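"""End-to-end pipeline: simulate -> zygosity -> features -> train -> predict
-> co-occurrence -> outcomes, with a checksummed manifest.

A run is fully determined by its config (one seed, deterministically split
per stage): rerunning the same config into a fresh directory produces
byte-identical outputs.
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
import yaml

from . import __version__
from .classifier import HrdsigClassifier, build_training_labels, labels_frame
from .cooccur import (
    compute_prevalence,
    cooccurrence_tests,
    landscape_partition,
)
from .features import features_frame
from .simulate import (
    Cohort,
    SimulationConfig,
    config_from_dict,
    config_to_dict,
    simulate_cohort,
    write_cohort,
)
from .survival import OutcomeAnalysis, brca_palb2_mutant_series
from .zygosity import call_sample_statuses, classify_hrr_sample, statuses_frame

logger = logging.getLogger(__name__)

MANIFEST_NAME = "manifest.json"


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass(frozen=True)
class PipelineConfig:
    out_dir: str = "hrdscar_run"
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    hyperparams: dict = field(default_factory=dict)
    n_folds: int = 5
    min_class_size: int = 20
    threshold_mode: str = "specificity"  # "specificity" | "prevalence"
    target_specificity: float = 0.95
    target_prevalence: float = 0.09

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("simulation", {})
        if "seed" in raw and "seed" not in sim:
            sim["seed"] = raw["seed"]
        return cls(simulation=config_from_dict(sim), **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"] = config_to_dict(self.simulation)
        return d


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_df(df: pd.DataFrame, path: Path, sep: str = ",") -> None:
    df.to_csv(path, sep=sep, index=False)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute all stages; returns the run directory.

    Any stage error aborts with the stage name; files written so far are
    recorded in a partial manifest.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, str] = {}
    stage = "configure"

    def record(path: Path) -> Path:
        written[path.name] = ""
        return path

    try:
        resolved = config.to_dict()
        resolved.pop("out_dir", None)  # implied by the run directory
        (out / "config.yaml").write_text(yaml.safe_dump(resolved, sort_keys=True))
        record(out / "config.yaml")

        stage = "simulate"
        t0 = time.monotonic()
        sim = dataclasses.replace(config.simulation, seed=config.seed)
        cohort = simulate_cohort(sim)
        paths = write_cohort(cohort, out)
        for p in paths.values():
            record(p)
        logger.info("simulate: %d patients in %.1fs", sim.n_patients,
                    time.monotonic() - t0)

        if sim.n_patients == 0:
            (out / "report.txt").write_text(
                "Empty cohort: 0 patients simulated; no analysis performed.\n"
            )
            record(out / "report.txt")
            _finalize_manifest(out, config, written)
            return out

        stage = "zygosity"
        per_sample = {}
        profile_by_id = {p.sample_id: p for p in cohort.profiles}
        variants_by_id: dict[str, list] = {pid: [] for pid in cohort.patient_ids}
        for v in cohort.variants:
            variants_by_id.setdefault(v.sample_id, []).append(v)
        for pid in cohort.patient_ids:
            per_sample[pid] = call_sample_statuses(
                pid, variants_by_id[pid], profile_by_id[pid]
            )
        statuses = statuses_frame(per_sample)
        _write_df(statuses, record(out / "allelic_status.csv"))
        classes = [classify_hrr_sample(pid, per_sample[pid]) for pid in cohort.patient_ids]

        stage = "features"
        feats = features_frame(cohort.profiles, cohort.variants)
        _write_df(feats.reset_index(), record(out / "scar_features.csv"))

        stage = "train"
        labels = build_training_labels(classes)
        _write_df(labels_frame(labels), record(out / "training_labels.csv"))
        model = HrdsigClassifier(feats, labels)
        results = model.fit(
            seed=config.seed,
            hyperparams=config.hyperparams,
            n_folds=config.n_folds,
            min_class_size=config.min_class_size,
        )
        if config.threshold_mode == "prevalence":
            results.select_threshold_by_prevalence(
                results.score(feats).to_numpy(), config.target_prevalence
            )
        else:
            results.select_threshold(config.target_specificity)
        results.save(out / "hrdsig_model.json")
        record(out / "hrdsig_model.json")
        record(out / "hrdsig_model.json.meta.json")

        stage = "predict"
        calls = results.predict(feats)
        _write_df(calls, record(out / "hrdsig_calls.csv"))

        stage = "cooccurrence"
        cooc = cooccurrence_tests(statuses, calls)
        _write_df(cooc, record(out / "cooccurrence.tsv"), sep="\t")
        partition = landscape_partition(statuses, calls)
        _write_df(partition.to_frame(), record(out / "landscape_partition.csv"))

        stage = "outcomes"
        brca_mut = brca_palb2_mutant_series(statuses)
        analysis = OutcomeAnalysis(cohort.clinical, calls, brca_mut)
        for endpoint in ("rwOS", "TTNT"):
            res = analysis.fit(endpoint=endpoint, seed=config.seed)
            _write_df(
                res.table, record(out / f"outcomes_{endpoint.lower()}.tsv"), sep="\t"
            )

        stage = "report"
        (out / "report.txt").write_text(report_summary(out))
        record(out / "report.txt")

        _finalize_manifest(out, config, written)
        return out
    except PipelineError:
        raise
    except Exception as err:  # noqa: BLE001 - stage attribution
        _finalize_manifest(out, config, written, failed_stage=stage)
        raise PipelineError(stage, str(err)) from err


def _finalize_manifest(
    out: Path, config: PipelineConfig, written: dict[str, str],
    failed_stage: str | None = None,
) -> None:
    checksums = {
        name: _sha256(out / name) for name in sorted(written) if (out / name).exists()
    }
    manifest = {
        "package": "hrdscar",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "files": checksums,
        "failed_stage": failed_stage,
    }
    (out / MANIFEST_NAME).write_text(json.dumps(manifest, indent=1, sort_keys=True))


def validate_manifest(run_dir) -> dict:
    """Re-hash run outputs against the manifest; raises on mismatch."""
    out = Path(run_dir)
    manifest = json.loads((out / MANIFEST_NAME).read_text())
    for name, digest in manifest["files"].items():
        actual = _sha256(out / name)
        if actual != digest:
            raise PipelineError("manifest", f"checksum mismatch for {name}")
    return manifest


def report_summary(run_dir) -> str:
    """Human-readable run summary (idempotent; reads only run outputs)."""
    out = Path(run_dir)
    required = ["hrdsig_calls.csv", "landscape_partition.csv",
                "cooccurrence.tsv", "outcomes_rwos.tsv"]
    missing = [f for f in required if not (out / f).exists()]
    if missing:
        raise PipelineError("report", f"incomplete run, missing files: {missing}")

    lines = ["HRDsig synthetic-cohort run summary", "=" * 36, ""]

    calls = pd.read_csv(out / "hrdsig_calls.csv")
    n_pos = int((calls["call"] == "positive").sum())
    lines += [
        "## HRDsig prevalence",
        f"simulated pancreatic carcinoma: {compute_prevalence(n_pos, len(calls))}% "
        f"({n_pos}/{len(calls)})" if len(calls) else "no samples",
        "",
    ]

    part = pd.read_csv(out / "landscape_partition.csv")
    lines.append("## Genomic landscape of HRDsig(+) samples")
    if n_pos == 0:
        lines.append("no positive samples")
    else:
        for r in part.itertuples():
            lines.append(f"{r.stratum}: {r.count} ({100 * r.fraction:.1f}%)")
    lines.append("")

    cooc = pd.read_csv(out / "cooccurrence.tsv", sep="\t")
    lines.append("## Co-occurrence with biallelic alterations (top hits)")
    if len(cooc) == 0:
        lines.append("no biallelically altered genes")
    else:
        top = cooc.sort_values("p_two_tailed").head(5)
        for r in top.itertuples():
            lines.append(
                f"{r.gene}: OR={r.odds_ratio_plot:.2f} p={r.p_two_tailed:.3g} "
                f"q={r.q_fdr:.3g}"
            )
    lines.append("")

    lines.append("## Stratified outcomes (FOLFIRINOX vs GP)")
    for endpoint in ("rwos", "ttnt"):
        path = out / f"outcomes_{endpoint}.tsv"
        if not path.exists():
            continue
        tab = pd.read_csv(path, sep="\t")
        lines.append(f"[{endpoint.upper()}]")
        for r in tab.itertuples():
            ahr = "n/a" if pd.isna(getattr(r, "ahr", float("nan"))) else (
                f"{r.ahr:.2f} ({r.ahr_lower_95:.2f}-{r.ahr_upper_95:.2f}), "
                f"p={r.ahr_p:.3g}"
            )
            med_f = "NR" if pd.isna(r.median_folfirinox) else f"{r.median_folfirinox:.1f}"
            med_g = "NR" if pd.isna(r.median_gp) else f"{r.median_gp:.1f}"
            lines.append(
                f"{r.stratum}: n={r.n}, median FOLF {med_f} vs GP {med_g} mo, "
                f"aHR {ahr}"
            )
        lines.append("")
    return "\n".join(lines) + "\n"
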