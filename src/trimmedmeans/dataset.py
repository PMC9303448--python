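"""Trial data container, trimming specification, and result records.

The CSV dialect read and written here is one row per participant with
columns ``id``, ``arm`` (0 = comparator, 1 = treatment), ``y`` (outcome;
empty cell = missing) and zero or more covariate columns (empty cell =
missing).
"""

from __future__ import annotations

import io
import json
import math
import os
from dataclasses import dataclass, field
import pandas as pd

__all__ = [
    "TrialDataset",
    "TrimSpec",
    "EstimateResult",
    "read_trial_csv",
    "write_trial_csv",
]

RESERVED_COLUMNS = ("arm", "y")


@dataclass
class TrialDataset:
    """Per-participant arm, outcome (missing allowed) and covariates.

    Wraps a :class:`pandas.DataFrame` with mandatory columns ``arm``
    (binary, never missing) and ``y`` (float, NaN = missing); any further
    columns are covariates and may contain NaN.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.frame
        for col in RESERVED_COLUMNS:
            if col not in df.columns:
                raise ValueError(f"trial data must contain an '{col}' column")
        if df["arm"].isna().any():
            bad = df.index[df["arm"].isna()][0]
            raise ValueError(f"participant {bad!r} has a missing arm label")
        arms = set(pd.unique(df["arm"]))
        if not arms <= {0, 1}:
            raise ValueError(f"arm codes must be 0/1, found {sorted(arms)}")
        counts = df["arm"].value_counts()
        for j in (0, 1):
            if counts.get(j, 0) < 2:
                raise ValueError(f"arm {j} has fewer than 2 participants")
        self.frame = df.astype({"arm": int, "y": float})

    # -- basic views ---------------------------------------------------
    @property
    def covariate_names(self) -> list[str]:
        return [c for c in self.frame.columns if c not in RESERVED_COLUMNS]

    def arm_frame(self, j: int) -> pd.DataFrame:
        return self.frame[self.frame["arm"] == j]

    @property
    def n_per_arm(self) -> dict[int, int]:
        return {j: int((self.frame["arm"] == j).sum()) for j in (0, 1)}

    @property
    def observed_counts(self) -> dict[int, int]:
        """Number of non-missing outcomes per arm."""
        obs = self.frame["y"].notna()
        return {j: int((obs & (self.frame["arm"] == j)).sum()) for j in (0, 1)}

    @property
    def dropout_proportions(self) -> dict[int, float]:
        n = self.n_per_arm
        m = self.observed_counts
        return {j: 1.0 - m[j] / n[j] for j in (0, 1)}

    def with_frame(self, frame: pd.DataFrame) -> "TrialDataset":
        return TrialDataset(frame)

    def equals(self, other: "TrialDataset") -> bool:
        a = self.frame.reset_index(drop=True)
        b = other.frame.reset_index(drop=True)
        return a.equals(b)


@dataclass(frozen=True)
class TrimSpec:
    """Trimming rule: fraction ``p``, trimmed tail, fixed or adaptive.

    ``direction`` names the tail trimmed *away* ("lower" removes the
    lowest fraction ``p``).  In fixed mode ``p`` must be at least the
    largest observed per-arm dropout proportion ``p_min``; adaptive mode
    sets ``p = p_min``.
    """

    fraction: float = 0.5
    direction: str = "lower"
    mode: str = "fixed"

    def __post_init__(self) -> None:
        if self.direction not in ("lower", "higher"):
            raise ValueError(f"direction must be 'lower' or 'higher', got {self.direction!r}")
        if self.mode not in ("fixed", "adaptive"):
            raise ValueError(f"mode must be 'fixed' or 'adaptive', got {self.mode!r}")
        if self.mode == "fixed" and not (0.0 <= self.fraction < 1.0):
            raise ValueError(f"trimming fraction must be in [0, 1), got {self.fraction}")

    def resolve(self, data: TrialDataset) -> float:
        """Effective trimming fraction for ``data``; validates feasibility."""
        drop = data.dropout_proportions
        p_min = max(drop.values())
        if self.mode == "adaptive":
            return p_min
        if self.fraction + 1e-12 < p_min:
            worst = max(drop, key=drop.get)
            raise ValueError(
                f"fixed trimming fraction p={self.fraction} is below the observed "
                f"dropout proportion {drop[worst]:.4f} in arm {worst} (p_min={p_min:.4f})"
            )
        return self.fraction

    @staticmethod
    def retained_count(n: int, p: float) -> int:
        """Ceiling rule: number of retained rows, ceil(n * (1 - p))."""
        return math.ceil(n * (1.0 - p) - 1e-9)


@dataclass
class EstimateResult:
    """A fitted treatment-effect estimate and its inference summary."""

    method: str
    estimate: float
    se: float | None = None
    ci: tuple[float, float] | None = None
    ci_level: float | None = None
    retained_per_arm: dict[int, int] | None = None
    p_used: float | None = None
    n_obs: int | None = None
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "estimate": self.estimate,
            "se": self.se,
            "ci": list(self.ci) if self.ci is not None else None,
            "ci_level": self.ci_level,
            "retained_per_arm": (
                {str(k): v for k, v in self.retained_per_arm.items()}
                if self.retained_per_arm is not None
                else None
            ),
            "p_used": self.p_used,
            "n_obs": self.n_obs,
            "warnings": list(self.warnings),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def to_text(self) -> str:
        lines = [f"method: {self.method}", f"estimate: {self.estimate:.6g}"]
        if self.se is not None:
            lines.append(f"se: {self.se:.6g}")
        if self.ci is not None:
            lo, hi = self.ci
            level = f" ({self.ci_level:.0%})" if self.ci_level else ""
            lines.append(f"ci{level}: [{lo:.6g}, {hi:.6g}]")
        if self.p_used is not None:
            lines.append(f"p_used: {self.p_used:.6g}")
        if self.retained_per_arm is not None:
            lines.append(
                "retained_per_arm: "
                + ", ".join(f"arm {j}: {n}" for j, n in sorted(self.retained_per_arm.items()))
            )
        for w in self.warnings:
            lines.append(f"warning: {w}")
        return "\n".join(lines)


def read_trial_csv(path: str | os.PathLike | io.TextIOBase) -> TrialDataset:
    """Read a participant-level trial CSV into a :class:`TrialDataset`.

    Mandatory columns ``id``, ``arm``, ``y``; empty cells are missing
    values.  Malformed arm codes or non-numeric outcomes raise a
    ``ValueError`` naming the offending row and column.
    """
    df = pd.read_csv(path, dtype={"id": str})
    for col in ("id", "arm", "y"):
        if col not in df.columns:
            raise ValueError(f"trial CSV is missing mandatory column '{col}'")
    if df["arm"].isna().any():
        row = df.index[df["arm"].isna()][0]
        raise ValueError(f"row {row}: column 'arm' is empty")
    try:
        arm = pd.to_numeric(df["arm"])
    except (ValueError, TypeError) as exc:
        raise ValueError(f"column 'arm' is not numeric: {exc}") from exc
    bad = ~arm.isin([0, 1])
    if bad.any():
        row = df.index[bad][0]
        raise ValueError(
            f"row {row}: column 'arm' has code {df.loc[row, 'arm']!r}; arm codes must be 0/1"
        )
    data_cols = {}
    for col in df.columns:
        if col == "id":
            continue
        try:
            data_cols[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise ValueError(f"column '{col}' is not numeric: {exc}") from exc
    out = pd.DataFrame(data_cols)
    out.index = df["id"].values
    return TrialDataset(out)


def write_trial_csv(data: TrialDataset, path: str | os.PathLike | io.TextIOBase) -> None:
    """Write ``data`` in the trial CSV dialect (round-trip stable)."""
    df = data.frame.copy()
    df.insert(0, "id", [str(i) for i in df.index])
    df.to_csv(path, index=False)
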