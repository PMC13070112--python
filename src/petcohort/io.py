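"""Delimited-text formats, run configuration and the pipeline driver.

TACs travel as TSV (``frame_start_s``, ``frame_dur_s``, then one activity
column per region); cohort tables as CSV. Every stage writes a JSON
sidecar recording the seed, configuration and input hashes so any stage
can be re-run in isolation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .curves import FrameSchedule, TimeActivityCurve
from .composites import (
    domain_and_general_scores,
    dat_composite,
    maob_pca_score,
    speed_score,
    zscore,
)
from .kinetics import PatlakConfig, fit_mrtm, fit_reference_patlak
from .stats import hierarchical_regression, log_lesion_transform, univariate_outliers
from .synthetic import (
    MAOB_PCA_REGIONS,
    CohortSpec,
    DEFAULT_DOMAIN_MAP,
    DEFAULT_TEST_BATTERY,
    generate_cohort,
)

__all__ = [
    "TacParseError",
    "RunConfig",
    "read_tac_table",
    "write_tac_table",
    "load_config",
    "run_pipeline",
    "simulate_stage",
    "fit_stage",
    "score_stage",
    "analyze_stage",
]

log = logging.getLogger("petcohort")
_FLOAT_FMT = "%.10g"


class TacParseError(ValueError):
    """A TAC table failed validation."""


def write_tac_table(path, schedule: FrameSchedule, curves: dict) -> None:
    """Write one TSV bundle: schedule columns plus one column per region."""
    cols = {"frame_start_s": schedule.start_s, "frame_dur_s": schedule.duration_s}
    for region, tac in curves.items():
        activity = tac.activity if isinstance(tac, TimeActivityCurve) else tac
        cols[region] = np.asarray(activity, dtype=float)
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_tac_table(path) -> dict[str, TimeActivityCurve]:
    """Read a TAC TSV bundle back into per-region curves.

    Raises :class:`TacParseError` naming the problem (missing schedule
    columns, non-contiguous frames, non-finite activity).
    """
    df = pd.read_csv(path, sep="\t")
    for col in ("frame_start_s", "frame_dur_s"):
        if col not in df.columns:
            raise TacParseError(f"{path}: missing required column {col!r}")
    regions = [c for c in df.columns if c not in ("frame_start_s", "frame_dur_s")]
    if not regions:
        raise TacParseError(f"{path}: no region columns")
    try:
        schedule = FrameSchedule(
            df["frame_start_s"].to_numpy(float), df["frame_dur_s"].to_numpy(float)
        )
    except ValueError as exc:
        raise TacParseError(f"{path}: invalid schedule: {exc}") from exc
    out = {}
    for region in regions:
        try:
            out[region] = TimeActivityCurve(
                schedule, df[region].to_numpy(float), region
            )
        except ValueError as exc:
            raise TacParseError(f"{path}: column {region!r}: {exc}") from exc
    return out


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

DEFAULT_MODELS = (
    {
        "name": "dat_model",
        "outcome": "dat_z",
        "blocks": [["age", "sex_male"], ["log_lesion_volume"], ["maob_factor"]],
    },
    {
        "name": "cognition_model",
        "outcome": "general_cognition",
        "blocks": [["age"], ["dat_z"], ["log_lesion_volume", "maob_factor"]],
    },
)


@dataclass
class RunConfig:
    """Configuration of the end-to-end pipeline."""

    seed: int = 0
    cohort: dict = field(default_factory=dict)  # CohortSpec overrides
    patlak: PatlakConfig = field(default_factory=PatlakConfig)
    reference_region: str = "cerebellum"
    require_all_domains: bool = True
    outlier_threshold_sd: float = 3.29
    models: list = field(default_factory=lambda: [dict(m) for m in DEFAULT_MODELS])

    def cohort_spec(self) -> CohortSpec:
        return CohortSpec(seed=self.seed, **self.cohort)


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    patlak_raw = raw.pop("patlak", {})
    if "fit_frames" in patlak_raw:
        patlak_raw["fit_frames"] = tuple(patlak_raw["fit_frames"])
    cfg = RunConfig(patlak=PatlakConfig(**patlak_raw), **raw)
    if cfg.cohort.get("n_subjects", 55) <= 1:
        raise ValueError("config invalid: cohort.n_subjects must be >= 2")
    return cfg


def _hash_file(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_sidecar(path, *, seed: int, stage: str, inputs=(), extra=None) -> None:
    payload = {
        "stage": stage,
        "seed": seed,
        "package_version": __version__,
        "inputs": {str(p): _hash_file(p) for p in inputs},
    }
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")


# --------------------------------------------------------------------------
# pipeline stages
# --------------------------------------------------------------------------


def simulate_stage(config: RunConfig, outdir: Path) -> Path:
    """Generate the synthetic cohort; write cohort CSV and TAC bundles."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = config.cohort_spec()
    cohort = generate_cohort(spec)
    cohort_csv = outdir / "cohort.csv"
    cohort.table.to_csv(cohort_csv, index=False, float_format=_FLOAT_FMT)
    if cohort.tacs is not None:
        tac_dir = outdir / "tacs"
        tac_dir.mkdir(exist_ok=True)
        for subject, bundles in cohort.tacs.items():
            for tracer, curves in bundles.items():
                write_tac_table(
                    tac_dir / f"{subject}_{tracer}.tsv",
                    next(iter(curves.values())).schedule,
                    curves,
                )
    spec_dict = dataclasses.asdict(spec)
    spec_dict.pop("construct_correlations", None)
    write_sidecar(
        outdir / "cohort.json",
        seed=config.seed,
        stage="simulate",
        extra={"spec": spec_dict},
    )
    return cohort_csv


def fit_stage(config: RunConfig, tac_dir: Path, out_csv: Path) -> Path:
    """Fit every TAC bundle; one row per subject x region x model."""
    tac_dir = Path(tac_dir)
    rows = []
    paths = sorted(tac_dir.glob("*.tsv"))
    if not paths:
        raise FileNotFoundError(f"no TAC bundles in {tac_dir}")
    for path in paths:
        subject, tracer = path.stem.rsplit("_", 1)
        curves = read_tac_table(path)
        if config.reference_region not in curves:
            raise TacParseError(f"{path}: no {config.reference_region!r} column")
        ref = curves[config.reference_region]
        for region, tac in curves.items():
            if region == config.reference_region:
                continue
            if tracer == "pe2i":
                fit = fit_mrtm(tac, ref)
            else:
                fit = fit_reference_patlak(tac, ref, config.patlak)
            rows.append(
                {
                    "subject_id": subject,
                    "tracer": tracer,
                    "region": region,
                    "model": fit.model,
                    "estimate": fit.estimate,
                    "intercept": fit.intercept,
                    "r_squared": fit.r_squared,
                }
            )
    out_csv = Path(out_csv)
    pd.DataFrame(rows).to_csv(out_csv, index=False, float_format=_FLOAT_FMT)
    write_sidecar(
        out_csv.with_suffix(".json"), seed=config.seed, stage="fit", inputs=paths
    )
    return out_csv


def _fits_to_wide(fits: pd.DataFrame) -> pd.DataFrame:
    wide = {}
    for (tracer, region), grp in fits.groupby(["tracer", "region"]):
        prefix = "bp_nd" if tracer == "pe2i" else "ki_ref"
        wide[f"{prefix}_{region}"] = grp.set_index("subject_id")["estimate"]
    return pd.DataFrame(wide)


def score_stage(
    config: RunConfig, cohort_csv: Path, out_csv: Path, fits_csv: Path | None = None
) -> Path:
    """Derive composites: DAT z, first-component factor score, cognition."""
    table = pd.read_csv(cohort_csv)
    inputs = [cohort_csv]
    if fits_csv is not None:
        fits = pd.read_csv(fits_csv)
        table = table.merge(
            _fits_to_wide(fits), left_on="subject_id", right_index=True, how="left"
        )
        inputs.append(fits_csv)
    else:  # fall back to simulator ground truth columns
        for col in [c for c in table.columns if c.startswith("bp_nd_true_")]:
            table[col.replace("bp_nd_true_", "bp_nd_")] = table[col]
        for col in [c for c in table.columns if c.startswith("ki_true_")]:
            table[col.replace("ki_true_", "ki_ref_")] = table[col]

    table["sex_male"] = (table["sex"] == "M").astype(int)
    table["dat_z"] = dat_composite(table["bp_nd_caudate"], table["bp_nd_putamen"])
    pca = maob_pca_score(table[[f"ki_ref_{r}" for r in MAOB_PCA_REGIONS]])
    table["maob_factor"] = pca.scores

    test_z = {}
    for test in DEFAULT_TEST_BATTERY:
        if test.domain == "speed":
            if f"{test.name}_n_correct" not in table.columns:
                continue
            raw = speed_score(
                table[f"{test.name}_n_correct"], table[f"{test.name}_total_rt_ms"]
            )
        elif test.name in table.columns:
            raw = table[test.name]
        else:
            continue
        test_z[test.name] = zscore(raw)
    scores = domain_and_general_scores(
        pd.DataFrame(test_z), DEFAULT_DOMAIN_MAP, config.require_all_domains
    )
    table = pd.concat([table, scores.add_suffix("_z").rename(
        columns={"general_cognition_z": "general_cognition"}
    )], axis=1)

    out_csv = Path(out_csv)
    table.to_csv(out_csv, index=False, float_format=_FLOAT_FMT)
    write_sidecar(
        out_csv.with_suffix(".json"),
        seed=config.seed,
        stage="score",
        inputs=inputs,
        extra={
            "pca_eigenvalues": list(pca.eigenvalues),
            "pca_loadings": [list(v) for v in pca.loadings.T],
            "pca_variables": list(pca.variables),
        },
    )
    return out_csv


def analyze_stage(config: RunConfig, scored_csv: Path, out_csv: Path) -> Path:
    """Outlier policy, lesion log-transform, hierarchical regressions."""
    table = pd.read_csv(scored_csv)

    report = univariate_outliers(
        table["lesion_volume_ml"], config.outlier_threshold_sd, name="lesion_volume_ml"
    )
    if report.n_flagged:
        log.info("flagging %d lesion-volume outlier(s)", report.n_flagged)
        table.loc[report.flagged_ids, "lesion_volume_ml"] = np.nan
    table["log_lesion_volume"], shape = log_lesion_transform(
        table["lesion_volume_ml"]
    )

    rows = []
    for model in config.models:
        results = hierarchical_regression(table, model["outcome"], model["blocks"])
        for i, res in enumerate(results, start=1):
            block = f"model{i}"
            rows.append(
                {
                    "model": model["name"], "block": block, "row_type": "model",
                    "variable": "", "f": res.f_statistic, "p": res.f_p_value,
                    "r_squared": res.r_squared, "adj_r_squared": res.adj_r_squared,
                    "n": res.n,
                }
            )
            for pred in res.predictors:
                rows.append(
                    {
                        "model": model["name"], "block": block, "row_type": "coef",
                        "variable": pred, "beta": res.beta[pred], "t": res.t[pred],
                        "partial_r": res.partial_r[pred], "p": res.p[pred],
                    }
                )
            if i > 1:
                rows.append(
                    {
                        "model": model["name"], "block": block,
                        "row_type": "r2_change", "variable": "",
                        "delta_r_squared": res.delta_r_squared,
                        "f": res.f_change, "p": res.p_change,
                        "df1": res.df_change[0], "df2": res.df_change[1],
                    }
                )
    out_csv = Path(out_csv)
    pd.DataFrame(rows).to_csv(out_csv, index=False, float_format=_FLOAT_FMT)
    write_sidecar(
        out_csv.with_suffix(".json"),
        seed=config.seed,
        stage="analyze",
        inputs=[scored_csv],
        extra={
            "lesion_outliers_flagged": report.n_flagged,
            "lesion_shape": shape,
        },
    )
    return out_csv


def run_pipeline(config: RunConfig, outdir) -> dict:
    """simulate -> fit -> score -> analyze, each stage logged and hashed."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts = {}
    stages = [
        ("simulate", lambda: simulate_stage(config, outdir)),
        (
            "fit",
            lambda: fit_stage(config, outdir / "tacs", outdir / "fits.csv")
            if (outdir / "tacs").exists()
            else None,
        ),
        (
            "score",
            lambda: score_stage(
                config,
                outdir / "cohort.csv",
                outdir / "scored.csv",
                fits_csv=artifacts.get("fit"),
            ),
        ),
        (
            "analyze",
            lambda: analyze_stage(config, outdir / "scored.csv", outdir / "results.csv"),
        ),
    ]
    for name, fn in stages:
        t0 = time.perf_counter()
        try:
            artifacts[name] = fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        log.info("stage %-8s done in %.2f s", name, time.perf_counter() - t0)
    return artifacts


def _configure_logging() -> None:
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s: %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
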