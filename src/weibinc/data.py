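"""Age-stratified incidence series and their CSV representation.

Empirical cumulative incidence is built from per-age diagnosis frequencies
``p_i`` by the exact product formula ``I(a) = 1 - prod_{i<=a}(1 - p_i)``,
never the rare-event sum approximation.  Ages are carried at bin midpoints
(``i + 0.5`` years for the 1-year bin labelled ``i``) everywhere downstream;
integer bin labels exist only at the reader/writer boundary.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AgeIncidenceSeries",
    "cumulative_incidence",
    "midpoint_ages",
    "read_incidence_table",
    "write_incidence_table",
]

DEFAULT_MAX_AGE = 85.0


def cumulative_incidence(p) -> np.ndarray:
    """Cumulative incidence ``I(a) = 1 - prod_{i=0}^{a}(1 - p_i)``.

    Parameters
    ----------
    p : array_like
        Per-age diagnosis frequencies, each in [0, 1].

    Returns
    -------
    ndarray of the same length, non-decreasing, in [0, 1].
    """
    p = np.asarray(p, dtype=float)
    bad = np.nonzero(~((p >= 0) & (p <= 1)))[0]
    if bad.size:
        raise ValueError(
            f"per-age frequency out of [0, 1] at bin index {bad[0]}: p={p[bad[0]]!r}"
        )
    return 1.0 - np.cumprod(1.0 - p)


def midpoint_ages(bins) -> np.ndarray:
    """Map integer 1-year age-bin labels to midpoint ages ``i + 0.5``."""
    bins = np.asarray(bins)
    if bins.size == 0:
        return np.asarray([], dtype=float)
    if not np.issubdtype(bins.dtype, np.integer):
        if not np.all(bins == np.floor(bins)):
            raise ValueError("bin labels must be integers")
    if np.any(bins < 0):
        raise ValueError("bin labels must be non-negative")
    return bins.astype(float) + 0.5


@dataclass
class AgeIncidenceSeries:
    """A labelled age-stratified cumulative incidence curve.

    Attributes
    ----------
    label : str
        Cancer type plus optional subgroup (registry/race/period/sex).
    ages : ndarray
        Strictly increasing midpoint ages in years.
    p : ndarray
        Per-age diagnosis frequency, each in [0, 1].
    cuminc : ndarray
        Cumulative incidence, the running product form of ``p``.
    diagnosed, at_risk : ndarray or None
        Optional per-bin counts with ``p = diagnosed / at_risk``.
    metadata : dict
        Free-form sidecar metadata (subgroup descriptors, simulation truth).
    """

    label: str
    ages: np.ndarray
    p: np.ndarray
    cuminc: np.ndarray = None
    diagnosed: np.ndarray = None
    at_risk: np.ndarray = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.ages = np.asarray(self.ages, dtype=float)
        self.p = np.asarray(self.p, dtype=float)
        if self.ages.ndim != 1 or self.ages.shape != self.p.shape:
            raise ValueError("ages and p must be 1-D arrays of equal length")
        if self.ages.size and np.any(np.diff(self.ages) <= 0):
            raise ValueError("ages must be strictly increasing")
        expected = cumulative_incidence(self.p)  # also validates p range
        if self.cuminc is None:
            self.cuminc = expected
        else:
            self.cuminc = np.asarray(self.cuminc, dtype=float)
            if self.cuminc.shape != self.p.shape:
                raise ValueError("cuminc must match p in length")
            if np.max(np.abs(self.cuminc - expected), initial=0.0) > 1e-12:
                raise ValueError("cuminc inconsistent with the product of (1 - p_i)")
        if (self.diagnosed is None) != (self.at_risk is None):
            raise ValueError("diagnosed and at_risk must be given together")
        if self.diagnosed is not None:
            self.diagnosed = np.asarray(self.diagnosed)
            self.at_risk = np.asarray(self.at_risk)
            if self.diagnosed.shape != self.p.shape or self.at_risk.shape != self.p.shape:
                raise ValueError("count columns must match p in length")
            if np.any(self.diagnosed < 0) or np.any(self.at_risk < 1):
                raise ValueError("diagnosed must be >= 0 and at_risk >= 1")
            if np.any(self.diagnosed > self.at_risk):
                raise ValueError("diagnosed must not exceed at_risk")
            ratio = self.diagnosed / self.at_risk
            if np.max(np.abs(ratio - self.p), initial=0.0) > 1e-12:
                raise ValueError("p must equal diagnosed / at_risk")

    @property
    def has_counts(self) -> bool:
        return self.diagnosed is not None

    def __len__(self) -> int:
        return self.ages.size

    @classmethod
    def from_frequencies(cls, label, bins, p, metadata=None):
        """Build a series from integer bin labels and per-bin frequencies."""
        return cls(label=label, ages=midpoint_ages(bins), p=np.asarray(p, float),
                   metadata=metadata or {})

    @classmethod
    def from_counts(cls, label, bins, diagnosed, at_risk, metadata=None):
        """Build a series from integer bin labels and diagnosis counts."""
        diagnosed = np.asarray(diagnosed)
        at_risk = np.asarray(at_risk)
        return cls(label=label, ages=midpoint_ages(bins),
                   p=diagnosed / at_risk, diagnosed=diagnosed, at_risk=at_risk,
                   metadata=metadata or {})

    def truncate(self, max_age: float = DEFAULT_MAX_AGE) -> "AgeIncidenceSeries":
        """Restrict the series to bins with midpoint age <= ``max_age``."""
        keep = self.ages <= max_age
        return AgeIncidenceSeries(
            label=self.label,
            ages=self.ages[keep],
            p=self.p[keep],
            diagnosed=None if self.diagnosed is None else self.diagnosed[keep],
            at_risk=None if self.at_risk is None else self.at_risk[keep],
            metadata=dict(self.metadata),
        )

    def to_frame(self) -> pd.DataFrame:
        cols = {"age": self.ages, "frequency": self.p, "cuminc": self.cuminc}
        if self.has_counts:
            cols["diagnosed"] = self.diagnosed
            cols["at_risk"] = self.at_risk
        return pd.DataFrame(cols)


def _validation_error(path, row, message):
    return ValueError(f"{path}: row {row}: {message}")


def read_incidence_table(path) -> AgeIncidenceSeries:
    """Read an age-stratified diagnosis table from CSV.

    The table must have a header with columns ``(age, diagnosed, at_risk)``
    or ``(age, frequency)``, one row per 1-year age bin.  ``#``-prefixed
    lines before the header carry metadata as ``# key: value``; a ``label``
    key names the series.  Midpoint ages are applied on read.
    """
    path = Path(path)
    metadata: dict = {}
    label = path.stem
    lines = path.read_text(encoding="utf-8").splitlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            body_start = i + 1
            stripped = line.lstrip("#").strip()
            if ":" in stripped:
                key, value = stripped.split(":", 1)
                key, value = key.strip(), value.strip()
                if key == "label":
                    label = value
                elif key == "metadata":
                    metadata.update(json.loads(value))
                else:
                    metadata[key] = value
        else:
            break
    df = pd.read_csv(io.StringIO("\n".join(lines[body_start:])),
                     float_precision="round_trip")
    cols = set(df.columns)
    if not ({"age", "diagnosed", "at_risk"} <= cols or {"age", "frequency"} <= cols):
        raise ValueError(
            f"{path}: expected columns (age, diagnosed, at_risk) or (age, frequency), "
            f"got {sorted(cols)}"
        )
    ages = df["age"].to_numpy()
    if np.any(ages != np.floor(ages)) or np.any(ages < 0):
        bad = int(np.nonzero((ages != np.floor(ages)) | (ages < 0))[0][0])
        raise _validation_error(path, bad + 2, f"age must be a non-negative integer, got {ages[bad]}")
    order = np.argsort(ages, kind="stable")
    df = df.iloc[order].reset_index(drop=True)
    ages = df["age"].to_numpy().astype(int)
    dup = np.nonzero(np.diff(ages) == 0)[0]
    if dup.size:
        raise _validation_error(path, int(dup[0]) + 3, f"duplicate age bin {ages[dup[0] + 1]}")

    if {"diagnosed", "at_risk"} <= cols:
        diagnosed = df["diagnosed"].to_numpy()
        at_risk = df["at_risk"].to_numpy()
        for name, arr in (("diagnosed", diagnosed), ("at_risk", at_risk)):
            neg = np.nonzero(arr < 0)[0]
            if neg.size:
                raise _validation_error(path, int(neg[0]) + 2, f"negative {name} count")
        over = np.nonzero(diagnosed > at_risk)[0]
        if over.size:
            raise _validation_error(path, int(over[0]) + 2, "diagnosed exceeds at_risk")
        return AgeIncidenceSeries.from_counts(label, ages, diagnosed, at_risk, metadata)
    freq = df["frequency"].to_numpy(dtype=float)
    bad = np.nonzero(~((freq >= 0) & (freq <= 1)))[0]
    if bad.size:
        raise _validation_error(path, int(bad[0]) + 2, f"frequency out of [0, 1]: {freq[bad[0]]}")
    return AgeIncidenceSeries.from_frequencies(label, ages, freq, metadata)


def write_incidence_table(series: AgeIncidenceSeries, path) -> None:
    """Write a series as CSV; ``read_incidence_table`` round-trips it exactly.

    Frequencies are written with 17 significant digits so the float values
    are reproduced bit-identically; metadata goes into ``#`` header lines.
    """
    path = Path(path)
    bins = np.round(series.ages - 0.5).astype(int)
    out = [f"# label: {series.label}"]
    if series.metadata:
        out.append("# metadata: " + json.dumps(series.metadata))
    if series.has_counts:
        out.append("age,diagnosed,at_risk")
        for b, x, n in zip(bins, series.diagnosed, series.at_risk):
            out.append(f"{b},{int(x)},{int(n)}")
    else:
        out.append("age,frequency")
        for b, f in zip(bins, series.p):
            out.append(f"{b},{float(f)!r}")
    path.write_text("\n".join(out) + "\n", encoding="utf-8")
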