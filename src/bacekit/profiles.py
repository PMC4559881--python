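"""Concentration–time profiles and tidy long-format CSV I/O.

A :class:`ConcentrationTimeProfile` is one subject's series of drug or
biomarker concentrations in one matrix (blood, brain, CSF or plasma).
Times are hours; negative times denote predose samples.  Samples below
the lower limit of quantification (BLQ) carry no numeric value and are
tracked in a boolean mask; the substitution rules used for area
calculations live in :mod:`bacekit.nca`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

MATRICES = frozenset({"blood", "brain", "csf", "plasma"})
ROUTES = frozenset({"po", "iv"})

#: long-format CSV columns expected by :func:`read_profiles_csv`
CSV_COLUMNS = (
    "subject_id",
    "matrix",
    "time_h",
    "conc",
    "unit",
    "lloq",
    "dose_umol_kg",
    "route",
)


class ProfileError(ValueError):
    """Invalid profile construction or an operation's precondition failed."""


@dataclass(frozen=True)
class ConcentrationTimeProfile:
    """One subject/matrix concentration–time series.

    Parameters
    ----------
    subject_id : str
        Subject identifier.
    matrix : {'blood', 'brain', 'csf', 'plasma'}
        Biological matrix the samples come from.
    times : ndarray of float
        Sampling times in hours, strictly increasing.  Negative times are
        predose samples.
    concentrations : ndarray of float
        Measured concentrations (uniform units within the profile).
        Entries flagged BLQ must be NaN.
    blq : ndarray of bool, optional
        True where the sample was below the limit of quantification.
    lloq : float
        Lower limit of quantification, in the profile's units; required
        to be > 0 whenever any sample is BLQ.
    dose : float
        Administered dose in μmol/kg (0 for biomarker series).
    route : {'po', 'iv'}
    unit : str
        Concentration unit label, e.g. ``'uM'`` or ``'pg/ml'``.
    """

    subject_id: str
    matrix: str
    times: np.ndarray
    concentrations: np.ndarray
    blq: np.ndarray | None = None
    lloq: float = 0.0
    dose: float = 0.0
    route: str = "po"
    unit: str = "uM"

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.concentrations, dtype=float)
        if t.ndim != 1 or c.shape != t.shape:
            raise ProfileError("times and concentrations must be 1-d and equal length")
        if t.size and np.any(np.diff(t) <= 0):
            raise ProfileError("times must be strictly increasing")
        blq = self.blq
        if blq is None:
            blq = np.zeros(t.shape, dtype=bool)
        else:
            blq = np.asarray(blq, dtype=bool)
            if blq.shape != t.shape:
                raise ProfileError("blq mask must match times")
        if np.any(blq & np.isfinite(c)):
            raise ProfileError("a sample cannot be both numeric and BLQ")
        if np.any(~blq & ~np.isfinite(c)):
            raise ProfileError("non-BLQ samples must be numeric")
        if np.any(c[~blq] < 0):
            raise ProfileError("concentrations must be >= 0")
        if blq.any() and not self.lloq > 0:
            raise ProfileError("lloq must be > 0 when BLQ samples are present")
        if self.matrix not in MATRICES:
            raise ProfileError(f"unknown matrix {self.matrix!r}")
        if self.route not in ROUTES:
            raise ProfileError(f"unknown route {self.route!r}")
        if self.dose < 0:
            raise ProfileError("dose must be >= 0")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "concentrations", c)
        object.__setattr__(self, "blq", blq)

    # -- masks -----------------------------------------------------------
    @property
    def numeric_mask(self) -> np.ndarray:
        """True where the sample has a quantifiable numeric value."""
        return ~self.blq

    @property
    def postdose_mask(self) -> np.ndarray:
        return self.times >= 0

    def n_quantifiable(self, postdose: bool = True) -> int:
        m = self.numeric_mask
        if postdose:
            m = m & self.postdose_mask
        return int(m.sum())

    def auc_concentrations(self) -> np.ndarray:
        """Concentrations with BLQ substituted for area calculations.

        BLQ samples before the first quantifiable point are set to 0;
        BLQ samples embedded in or after the quantifiable range are set
        to LLOQ/2.  This is the standard sparse-sampling NCA convention.
        """
        c = self.concentrations.copy()
        if not self.blq.any():
            return c
        numeric_idx = np.flatnonzero(self.numeric_mask)
        if numeric_idx.size == 0:
            raise ProfileError("no quantifiable concentration in profile")
        first = numeric_idx[0]
        for i in np.flatnonzero(self.blq):
            c[i] = 0.0 if i < first else self.lloq / 2.0
        return c

    def with_(self, **changes) -> "ConcentrationTimeProfile":
        return replace(self, **changes)

    def to_frame(self) -> pd.DataFrame:
        conc = np.where(self.blq, np.nan, self.concentrations)
        return pd.DataFrame(
            {
                "subject_id": self.subject_id,
                "matrix": self.matrix,
                "time_h": self.times,
                "conc": conc,
                "blq": self.blq,
                "unit": self.unit,
                "lloq": self.lloq,
                "dose_umol_kg": self.dose,
                "route": self.route,
            }
        )


def read_profiles_csv(path: str | Path, matrix: str | None = None) -> list[ConcentrationTimeProfile]:
    """Read long-format profiles (one row per sample) from a CSV file.

    The ``conc`` column may contain the literal string ``BLQ`` (case
    insensitive) for censored samples.  Rows are grouped into one profile
    per (subject_id, matrix) pair, sorted by time.
    """
    df = pd.read_csv(path, dtype={"subject_id": str, "conc": str})
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ProfileError(f"missing CSV columns: {missing}")
    if matrix is not None:
        df = df[df["matrix"] == matrix]
    profiles = []
    for (sid, mat), grp in df.groupby(["subject_id", "matrix"], sort=True):
        grp = grp.sort_values("time_h")
        raw = grp["conc"].astype(str).str.strip()
        blq = raw.str.upper().eq("BLQ").to_numpy()
        conc = pd.to_numeric(raw.where(~blq), errors="raise").to_numpy(dtype=float)
        profiles.append(
            ConcentrationTimeProfile(
                subject_id=str(sid),
                matrix=str(mat),
                times=grp["time_h"].to_numpy(dtype=float),
                concentrations=conc,
                blq=blq,
                lloq=float(grp["lloq"].iloc[0]),
                dose=float(grp["dose_umol_kg"].iloc[0]),
                route=str(grp["route"].iloc[0]),
                unit=str(grp["unit"].iloc[0]),
            )
        )
    return profiles


def write_profiles_csv(profiles: list[ConcentrationTimeProfile], path: str | Path) -> None:
    frames = []
    for p in profiles:
        f = p.to_frame()
        f["conc"] = [
            "BLQ" if b else repr(float(v)) for v, b in zip(p.concentrations, p.blq)
        ]
        frames.append(f.drop(columns="blq"))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
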