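"""Property datasets, stratified splitting, metrics and the model benchmark.

A property dataset holds rows of (mixture spec, label) for one of three
deep-eutectic-solvent properties: density (g/mL), viscosity (cP) or
melting temperature (K).  Density and viscosity are functions of both
composition and temperature; melting temperature of composition only.

The three-way hold-out splits each dataset into training (70%),
validation (20%) and testing (10%) subsets by stratified sampling on
quantile bins of the label, so every subset sees the full label range.
Kernel and normalization choices are benchmarked by fitting one GP per
(kernel family x label normalization) cell on the training split and
scoring validation R^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .gp import KERNEL_FAMILIES, NORMALIZATION_MODES, TrainedGP, train_gp
from .profiles import MixtureSpec, SigmaProfile, featurize_many

__all__ = [
    "PROPERTIES",
    "PROPERTY_UNITS",
    "PropertyDataset",
    "SplitSpec",
    "Metrics",
    "LoadReport",
    "load_dataset",
    "save_dataset",
    "stratified_split",
    "evaluate",
    "benchmark_grid",
    "dataset_to_matrices",
]

PROPERTY_UNITS = {
    "density": "g/mL",
    "viscosity": "cP",
    "melting_temperature": "K",
}
PROPERTIES = tuple(PROPERTY_UNITS)

# Density and viscosity depend on the system temperature; melting point
# is a property of the composition alone.
_USES_TEMPERATURE = {"density": True, "viscosity": True, "melting_temperature": False}

DATASET_COLUMNS = ["comp1", "comp2", "comp3", "x1", "x2", "x3", "temperature_K", "label"]


@dataclass
class PropertyDataset:
    """Labelled mixtures for one physical property."""

    property_name: str
    rows: list[tuple[MixtureSpec, float]]

    def __post_init__(self) -> None:
        if self.property_name not in PROPERTIES:
            raise ValueError(f"unknown property {self.property_name!r}")
        uses_t = self.uses_temperature
        for spec, label in self.rows:
            if not np.isfinite(label):
                raise ValueError(f"non-finite label {label!r}")
            if self.property_name in ("density", "viscosity") and label <= 0:
                raise ValueError(
                    f"{self.property_name} labels must be > 0, got {label!r}"
                )
            if uses_t != (spec.temperature is not None):
                raise ValueError(
                    f"{self.property_name}: temperature "
                    f"{'required' if uses_t else 'not allowed'} on every row"
                )

    @property
    def uses_temperature(self) -> bool:
        return _USES_TEMPERATURE[self.property_name]

    @property
    def labels(self) -> np.ndarray:
        return np.array([y for _, y in self.rows])

    def __len__(self) -> int:
        return len(self.rows)

    def subset(self, indices: Sequence[int]) -> "PropertyDataset":
        return PropertyDataset(self.property_name, [self.rows[i] for i in indices])


@dataclass(frozen=True)
class SplitSpec:
    """Index partition for the three-way hold-out."""

    train: tuple[int, ...]
    validation: tuple[int, ...]
    test: tuple[int, ...]
    fractions: tuple[float, float, float]
    n_strata: int
    seed: int

    def __post_init__(self) -> None:
        parts = [set(self.train), set(self.validation), set(self.test)]
        total = sum(len(p) for p in parts)
        if len(set().union(*parts)) != total:
            raise ValueError("split index lists overlap")


@dataclass(frozen=True)
class Metrics:
    """Regression metrics: R^2, MAE and (viscosity only) MALE in log10."""

    r2: float
    mae: float
    male: float | None = None


@dataclass
class LoadReport:
    """Result of loading a dataset table: accepted rows plus rejections."""

    dataset: PropertyDataset
    rejections: list[tuple[int, str]] = field(default_factory=list)


def load_dataset(
    source,
    property_name: str,
    profiles: Mapping[str, SigmaProfile] | None = None,
) -> LoadReport:
    """Read a delimited table of mixtures into a validated dataset.

    Expected columns: comp1..comp3, x1..x3, temperature_K, label
    (comp3/x3 blank for binaries, comp2/x2 too for pure compounds;
    temperature_K blank for melting-temperature data).  Malformed rows —
    fractions not summing to one, unknown compound ids, bad labels — are
    collected in the rejection report with a reason, never silently
    dropped.  Raises if no row survives.
    """
    if isinstance(source, pd.DataFrame):
        df = source
    else:
        df = pd.read_csv(source, float_precision="round_trip")
    missing = [c for c in DATASET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"dataset table lacks columns {missing}")
    uses_t = _USES_TEMPERATURE[property_name]
    rows: list[tuple[MixtureSpec, float]] = []
    rejections: list[tuple[int, str]] = []
    for idx, rec in df.iterrows():
        try:
            comps = []
            for k in (1, 2, 3):
                cid, x = rec[f"comp{k}"], rec[f"x{k}"]
                if pd.isna(cid) or (isinstance(cid, str) and not cid.strip()):
                    continue
                comps.append((str(cid).strip(), float(x)))
            xs = sum(x for _, x in comps)
            if abs(xs - 1.0) > 1e-6:
                raise ValueError(f"mole fractions sum to {xs:.6g}, not 1")
            temp = rec["temperature_K"]
            temp = None if pd.isna(temp) else float(temp)
            if uses_t and temp is None:
                raise ValueError("temperature_K required for this property")
            if not uses_t:
                temp = None
            spec = MixtureSpec(tuple(comps), temperature=temp)
            if profiles is not None:
                unknown = [c for c, _ in comps if c not in profiles]
                if unknown:
                    raise KeyError(f"unknown compound ids {unknown}")
            label = float(rec["label"])
            if not np.isfinite(label):
                raise ValueError("non-finite label")
            if property_name in ("density", "viscosity") and label <= 0:
                raise ValueError(f"{property_name} label must be > 0")
            rows.append((spec, label))
        except (ValueError, KeyError) as exc:
            rejections.append((int(idx), str(exc)))
    if not rows:
        raise ValueError(
            f"no valid rows loaded ({len(rejections)} rejected); "
            f"first reason: {rejections[0][1] if rejections else 'empty table'}"
        )
    return LoadReport(PropertyDataset(property_name, rows), rejections)


def save_dataset(ds: PropertyDataset, path) -> None:
    """Write a dataset back to the CSV layout accepted by load_dataset."""
    records = []
    for spec, label in ds.rows:
        rec = dict.fromkeys(DATASET_COLUMNS, np.nan)
        for k, (cid, x) in enumerate(spec.components, start=1):
            rec[f"comp{k}"] = cid
            rec[f"x{k}"] = x
        if spec.temperature is not None:
            rec["temperature_K"] = spec.temperature
        rec["label"] = label
        records.append(rec)
    pd.DataFrame.from_records(records, columns=DATASET_COLUMNS).to_csv(
        path, index=False, float_format="%.17g"
    )


def stratified_split(
    ds: PropertyDataset,
    fractions: tuple[float, float, float] = (0.70, 0.20, 0.10),
    n_strata: int = 10,
    seed: int = 0,
) -> SplitSpec:
    """Three-way hold-out with label-stratified sampling.

    Labels are binned into ``n_strata`` equal-frequency (quantile) bins;
    within each bin rows are shuffled by ``seed`` and allotted to
    train/validation/test by the largest-remainder rule, so realized
    global fractions are exact to within one row per stratum.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    if n_strata < 1:
        raise ValueError("n_strata must be >= 1")
    labels = ds.labels
    n = len(labels)
    edges = np.quantile(labels, np.linspace(0, 1, n_strata + 1))
    # searchsorted on interior edges; duplicates collapse harmlessly
    bins = np.searchsorted(edges[1:-1], labels, side="right")
    rng = np.random.default_rng(seed)
    parts: tuple[list[int], list[int], list[int]] = ([], [], [])
    for b in np.unique(bins):
        members = np.flatnonzero(bins == b)
        rng.shuffle(members)
        counts = _largest_remainder(len(members), fractions)
        offset = 0
        for part, c in zip(parts, counts):
            part.extend(int(i) for i in members[offset : offset + c])
            offset += c
    return SplitSpec(
        train=tuple(sorted(parts[0])),
        validation=tuple(sorted(parts[1])),
        test=tuple(sorted(parts[2])),
        fractions=fractions,
        n_strata=n_strata,
        seed=seed,
    )


def _largest_remainder(total: int, fractions: Sequence[float]) -> list[int]:
    raw = [total * f for f in fractions]
    counts = [int(np.floor(r)) for r in raw]
    short = total - sum(counts)
    remainders = sorted(
        range(len(fractions)), key=lambda i: (raw[i] - counts[i]), reverse=True
    )
    for i in remainders[:short]:
        counts[i] += 1
    return counts


def evaluate(
    predicted: np.ndarray, observed: np.ndarray, property_name: str
) -> Metrics:
    """R^2, MAE and — for viscosity — MALE (mean |log10 y - log10 yhat|)."""
    predicted = np.asarray(predicted, dtype=float).ravel()
    observed = np.asarray(observed, dtype=float).ravel()
    if predicted.shape != observed.shape or predicted.size < 2:
        raise ValueError("predicted and observed must share length >= 2")
    resid = observed - predicted
    ss_res = float(resid @ resid)
    centered = observed - observed.mean()
    ss_tot = float(centered @ centered)
    if ss_tot == 0.0:
        warnings.warn("zero label variance: R^2 undefined", stacklevel=2)
        r2 = float("nan")
    else:
        r2 = 1.0 - ss_res / ss_tot
    mae = float(np.abs(resid).mean())
    male = None
    if property_name == "viscosity":
        if np.all(predicted > 0) and np.all(observed > 0):
            male = float(
                np.abs(np.log10(observed) - np.log10(predicted)).mean()
            )
        else:
            warnings.warn("nonpositive values: MALE undefined", stacklevel=2)
            male = float("nan")
    return Metrics(r2=r2, mae=mae, male=male)


def dataset_to_matrices(
    ds: PropertyDataset, profiles: Mapping[str, SigmaProfile]
) -> tuple[np.ndarray, np.ndarray]:
    """Featurize every row: (n, 183 or 184) matrix and (n,) label vector."""
    X = featurize_many(profiles, [spec for spec, _ in ds.rows])
    return X, ds.labels


def benchmark_grid(
    ds: PropertyDataset,
    split: SplitSpec,
    profiles: Mapping[str, SigmaProfile],
    seed: int = 0,
    feature_mode: str = "log_standardize",
    extended: bool = False,
    n_restarts: int = 2,
) -> pd.DataFrame:
    """Validation R^2 for every kernel x label-normalization combination.

    The default grid is 3 kernels x 3 label modes = 9 cells with feature
    normalization fixed to log-standardization; ``extended=True`` also
    varies the feature mode (27 cells).  Each cell trains on the training
    split only and scores on validation; a failed fit becomes a row with
    status ``failed`` rather than aborting the sweep.  Rows are sorted by
    validation R^2 (descending), ties broken by kernel name.
    """
    X, y = dataset_to_matrices(ds, profiles)
    Xtr, ytr = X[list(split.train)], y[list(split.train)]
    Xva, yva = X[list(split.validation)], y[list(split.validation)]
    feature_modes = list(NORMALIZATION_MODES) if extended else [feature_mode]
    records = []
    for fmode in feature_modes:
        for family in KERNEL_FAMILIES:
            for lmode in NORMALIZATION_MODES:
                rec = {
                    "kernel": family,
                    "feature_normalization": fmode,
                    "label_normalization": lmode,
                    "val_r2": np.nan,
                    "val_mae": np.nan,
                    "status": "ok",
                }
                try:
                    model = train_gp(
                        Xtr, ytr, family=family,
                        feature_mode=fmode, label_mode=lmode,
                        n_restarts=n_restarts, seed=seed,
                    )
                    pred = model.predict(Xva)
                    m = evaluate(pred.mean, yva, ds.property_name)
                    r2 = m.r2
                    if ds.property_name == "viscosity":
                        # viscosity is analyzed on the log scale; a model
                        # whose predictions go nonpositive scores NaN
                        if np.all(pred.mean > 0):
                            with np.errstate(invalid="ignore"):
                                r2 = evaluate(
                                    np.log10(pred.mean), np.log10(yva),
                                    "density",
                                ).r2
                        else:
                            r2 = np.nan
                    rec["val_r2"], rec["val_mae"] = r2, m.mae
                except Exception as exc:  # noqa: BLE001 — record, don't abort
                    rec["status"] = f"failed: {exc}"
                records.append(rec)
    df = pd.DataFrame.from_records(records)
    df = df.sort_values(
        ["val_r2", "kernel"], ascending=[False, True], na_position="last"
    ).reset_index(drop=True)
    return df
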