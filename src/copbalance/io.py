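"""File formats, run configuration, and end-to-end pipeline orchestration.

The canonical on-disk form of a COP dataset is a long-format UTF-8 CSV with
columns ``patient_id, diagnosis, age, condition, axis, sample_index, value``
(0-based contiguous sample_index per trial, axis in {ML, AP}, condition in
1..6) plus a patient-metadata CSV ``patient_id, diagnosis, age``.  Long
format was chosen over wide so ragged cohorts remain representable and every
row is independently validatable.

`run_pipeline` executes the full analysis — simulate, detrend, entropy,
screen, train — writing each stage's artifact together with the fully
resolved configuration, so a run is reproducible from its output directory
alone.  All randomness flows from a single master seed that is split per
stage.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classify as classify_mod
from . import emd as emd_mod
from . import stats as stats_mod
from . import synthetic as syn
from .apen import ApEnParams, apen as _apen

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "write_cop_csv",
    "read_cop_dataset",
    "write_metadata_csv",
    "read_metadata_csv",
    "detrend_trials",
    "apen_table",
    "run_pipeline",
]

COP_COLUMNS = ["patient_id", "diagnosis", "age", "condition", "axis", "sample_index", "value"]


@dataclass(frozen=True)
class RunConfig:
    """Every tunable of the pipeline in one validated document."""

    seed: int = 0
    # cohort
    class_sizes: dict = field(
        default_factory=lambda: {"NormalBalance": 130, "Imbalance": 185, "TBI": 103, "UVWRight": 57}
    )
    regularity_base: dict = field(
        default_factory=lambda: {"NormalBalance": 0.60, "Imbalance": 0.48, "TBI": 0.35, "UVWRight": 0.46}
    )
    regularity_slope: float = 0.02
    trend_amplitude: float = 1.0
    trend_band: tuple = (0.01, 0.08)
    sampling_rate: float = 100.0
    duration: float = 20.0
    # detrending
    epsilon: float = emd_mod.DEFAULT_EPSILON
    k_imfs: int = emd_mod.DETREND_IMFS
    max_imfs: int = emd_mod.DEFAULT_MAX_IMFS
    max_iterations: int = emd_mod.DEFAULT_MAX_ITERATIONS
    # entropy
    apen_m: int = 2
    apen_r: float = 0.2
    apen_r_mode: str = "relative"
    n_shuffles: int = 20
    # screening
    age_cut: float = stats_mod.DEFAULT_AGE_CUT
    alpha: float = stats_mod.DEFAULT_ALPHA
    screening_mode: str = "all_features"
    # classification
    test_size: float = classify_mod.DEFAULT_TEST_SIZE
    positive_class: str = classify_mod.DEFAULT_POSITIVE_CLASS

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "trend_band" in raw:
            raw["trend_band"] = tuple(raw["trend_band"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["trend_band"] = list(self.trend_band)
        return d

    def cohort_config(self, seed: int | None = None) -> syn.CohortConfig:
        labels = {label.value: label for label in syn.DiagnosisLabel}
        base = {labels[k]: v for k, v in self.regularity_base.items()}
        return syn.CohortConfig(
            class_sizes={labels[k]: v for k, v in self.class_sizes.items()},
            regularity=syn.regularity_profile(base, self.regularity_slope),
            trend_band=tuple(self.trend_band),
            trend_amplitude=self.trend_amplitude,
            sampling_rate=self.sampling_rate,
            duration=self.duration,
            seed=self.seed if seed is None else seed,
        )

    def apen_params(self) -> ApEnParams:
        return ApEnParams(m=self.apen_m, r=self.apen_r, r_mode=self.apen_r_mode)


# ---------------------------------------------------------------------------
# dataset serialisation


def write_cop_csv(patients, trials, path) -> None:
    """Write the long-format COP CSV (one row per sample)."""
    ages = {p.patient_id: p.age for p in patients}
    frames = []
    for trial in trials:
        n = trial.samples.size
        frames.append(
            pd.DataFrame(
                {
                    "patient_id": np.repeat(trial.patient_id, n),
                    "diagnosis": np.repeat(str(trial.diagnosis.value), n),
                    "age": np.repeat(ages[trial.patient_id], n),
                    "condition": np.repeat(trial.condition, n),
                    "axis": np.repeat(trial.axis, n),
                    "sample_index": np.arange(n),
                    "value": trial.samples,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_cop_dataset(path):
    """Read and validate a long-format COP CSV.

    Returns ``(patients, trials)``.  Violations — unknown axis or condition,
    non-numeric values, gaps in sample_index — raise ValueError naming the
    offending trial or line.
    """
    df = pd.read_csv(path, dtype={"patient_id": str, "axis": str, "diagnosis": str})
    missing = set(COP_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"COP CSV missing columns: {sorted(missing)}")
    bad_axis = ~df["axis"].isin(syn.AXES)
    if bad_axis.any():
        bad = df.loc[bad_axis, "axis"].iloc[0]
        raise ValueError(f"invalid axis {bad!r}; admissible axes are {list(syn.AXES)}")
    bad_cond = ~df["condition"].isin(syn.CONDITIONS)
    if bad_cond.any():
        bad = df.loc[bad_cond, "condition"].iloc[0]
        raise ValueError(f"invalid condition {bad!r}; admissible conditions are 1..6")
    values = pd.to_numeric(df["value"], errors="coerce")
    if values.isna().any():
        line = int(values.index[values.isna()][0]) + 2  # header + 1-based
        raise ValueError(f"non-numeric COP value at line {line}")
    df["value"] = values

    labels = {label.value: label for label in syn.DiagnosisLabel}
    patients, trials = [], []
    seen = set()
    for (pid, cond, axis), group in df.groupby(
        ["patient_id", "condition", "axis"], sort=True
    ):
        idx = group["sample_index"].to_numpy()
        order = np.argsort(idx)
        idx = idx[order]
        expected = np.arange(idx.size)
        if not np.array_equal(idx, expected):
            raise ValueError(
                f"sample_index not contiguous 0..N-1 for "
                f"(patient={pid}, condition={cond}, axis={axis})"
            )
        diagnosis = labels.get(group["diagnosis"].iloc[0])
        if diagnosis is None:
            raise ValueError(f"unknown diagnosis {group['diagnosis'].iloc[0]!r}")
        if pid not in seen:
            seen.add(pid)
            patients.append(
                syn.PatientRecord(pid, diagnosis, float(group["age"].iloc[0]))
            )
        trials.append(
            syn.CopTrial(
                patient_id=pid,
                diagnosis=diagnosis,
                condition=int(cond),
                axis=str(axis),
                samples=group["value"].to_numpy()[order],
                sampling_rate=100.0,
            )
        )
    return patients, trials


def write_metadata_csv(patients, path) -> None:
    pd.DataFrame(
        {
            "patient_id": [p.patient_id for p in patients],
            "diagnosis": [p.diagnosis.value for p in patients],
            "age": [p.age for p in patients],
        }
    ).to_csv(path, index=False)


def read_metadata_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"patient_id": str, "diagnosis": str})
    missing = {"patient_id", "diagnosis", "age"} - set(df.columns)
    if missing:
        raise ValueError(f"metadata CSV missing columns: {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# pipeline stages


def detrend_trials(trials, config: RunConfig):
    """EMD-detrend every trial; returns new trials with detrended samples."""
    out = []
    for trial in trials:
        dec = emd_mod.decompose(
            trial.samples,
            epsilon=config.epsilon,
            max_imfs=config.max_imfs,
            max_iterations=config.max_iterations,
        )
        detrended = emd_mod.detrend(trial.samples, dec, k=config.k_imfs)
        out.append(dataclasses.replace(trial, samples=detrended))
    return out


def apen_table(trials, params: ApEnParams) -> pd.DataFrame:
    """Per-trial ApEn records (patient_id, condition, axis, m, r_mode, r, apen)."""
    rows = []
    for trial in trials:
        result = _apen(trial.samples, params)
        rows.append(
            {
                "patient_id": trial.patient_id,
                "condition": trial.condition,
                "axis": trial.axis,
                "m": params.m,
                "r_mode": params.r_mode,
                "r": params.r,
                "apen": result.value,
            }
        )
    return pd.DataFrame(rows)


class _WarningCounter(logging.Handler):
    def __init__(self):
        super().__init__(level=logging.WARNING)
        self.counts: dict[str, int] = {}

    def emit(self, record):
        self.counts[record.name] = self.counts.get(record.name, 0) + 1


def run_pipeline(config: RunConfig, out_dir, write_raw: bool = True) -> dict:
    """Execute simulate -> detrend -> entropy -> screen -> train.

    Writes every stage artifact plus the resolved configuration into
    ``out_dir`` and returns a summary dict.  Deterministic given the config.
    ``write_raw=False`` skips the (large) per-sample raw and detrended CSVs
    and keeps only the derived artifacts.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counter = _WarningCounter()
    logging.getLogger("copbalance").addHandler(counter)
    try:
        ss = np.random.SeedSequence(config.seed)
        cohort_seed, train_seed = (
            int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(2)
        )

        logger.info("stage simulate")
        cohort_cfg = config.cohort_config(seed=cohort_seed)
        patients, trials = syn.generate_cohort(cohort_cfg)
        write_metadata_csv(patients, out / "metadata.csv")
        if write_raw:
            write_cop_csv(patients, trials, out / "cop.csv")

        logger.info("stage detrend (%d trials)", len(trials))
        detrended = detrend_trials(trials, config)
        if write_raw:
            write_cop_csv(patients, detrended, out / "cop_detrended.csv")

        logger.info("stage entropy")
        params = config.apen_params()
        table = apen_table(detrended, params)
        table.to_csv(out / "apen.csv", index=False)

        features = classify_mod.assemble_features(table)
        features.to_csv(out / "features.csv")
        metadata = read_metadata_csv(out / "metadata.csv")

        logger.info("stage screen")
        screening = stats_mod.screen_pairs(
            features,
            metadata,
            age_cut=config.age_cut,
            alpha=config.alpha,
            mode=config.screening_mode,
        )
        (out / "screening.json").write_text(json.dumps(screening.to_dict(), indent=2))

        logger.info("stage train")
        meta = metadata.set_index("patient_id").loc[features.index]
        pair = screening.selected_pair or ("NormalBalance", "TBI")
        older = meta["age"] > config.age_cut
        in_pair = meta["diagnosis"].isin(pair)
        binary_mask = (older & in_pair).to_numpy()
        reports = {}
        if binary_mask.sum() >= 10 and meta.loc[binary_mask, "diagnosis"].nunique() == 2:
            positive = (
                config.positive_class
                if config.positive_class in pair
                else pair[1]
            )
            reports["binary_over47"] = classify_mod.evaluate_models(
                features.loc[binary_mask],
                meta.loc[binary_mask, "diagnosis"].to_numpy(),
                approach="binary_over47",
                seed=train_seed,
                test_size=config.test_size,
                positive_class=positive,
            )
        reports["fourclass_all"] = classify_mod.evaluate_models(
            features,
            meta["diagnosis"].to_numpy(),
            approach="fourclass_all",
            seed=train_seed,
            test_size=config.test_size,
        )
        report_dict = {name: rep.to_dict() for name, rep in reports.items()}
        (out / "classifier_report.json").write_text(json.dumps(report_dict, indent=2))
        for name, rep in reports.items():
            rep.to_frame().to_csv(out / f"table_{name}.csv")

        summary = {
            "n_patients": len(patients),
            "n_trials": len(trials),
            "selected_pair": list(pair),
            "approaches": sorted(reports),
            "warnings": counter.counts,
            "resolved_config": config.to_dict(),
        }
        (out / "resolved_config.yaml").write_text(yaml.safe_dump(config.to_dict()))
        (out / "summary.json").write_text(json.dumps(summary, indent=2))
        logger.info("pipeline complete: %s", {k: v for k, v in summary.items() if k != "resolved_config"})
        return summary
    finally:
        logging.getLogger("copbalance").removeHandler(counter)
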