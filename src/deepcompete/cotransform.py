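"""Double-transformant estimation from two-marker plating counts.

A culture transformed with an equimolar mix of a URA3- and a LEU2-marked
plasmid is plated on -ura, -leu and -ura-leu media.  Only cells carrying
both markers grow on the double dropout; assuming co-transformed cells split
25% ura/ura : 50% ura/leu : 25% leu/leu, the visible double-marker colonies
are half of all doubles, hence the factor 2 in the estimators.

Post-transformation estimate:   2 nAB / (nA + nB - nAB) * 100%
Post-selection estimate:        2 nAB / (nA - nAB) * 100%

(after selection only ura-marked cells survive, so -leu plating is
uninformative and the total transformant count is nA - nAB).  Plate counts
are first scaled to whole-culture numbers by a pooled ratio-of-sums
estimator over the plated culture fractions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ztp import eq1_bias, eq1_expectation, ztp_multi_fraction

__all__ = [
    "scale_to_culture",
    "percent_double_posttransform",
    "percent_double_postselection",
    "summarize_replicates",
    "DoubleTransformantEstimate",
    "DoubleTransformantModel",
    "DoubleTransformantResults",
    "read_plates_csv",
]

PLATE_CLASSES = ("sel_A", "sel_B", "sel_AB")


@dataclass
class DoubleTransformantEstimate:
    """One culture's estimate: percent of cells with >= 2 plasmids."""

    percent_double: float
    total_transformants: float
    valid: bool = True  # False when the estimate exceeds 100% (violated assumptions)


def scale_to_culture(plates: pd.DataFrame) -> pd.Series:
    """Whole-culture colony counts per plate class.

    Pools replicate plates of a class with the ratio-of-sums estimator
    sum(colonies) / sum(plated_fraction), which is robust to individual
    low-count plates.
    """
    if not {"plate_class", "colonies", "plated_fraction"} <= set(plates.columns):
        raise ValueError("plates need columns plate_class, colonies, plated_fraction")
    if (plates["plated_fraction"] <= 0).any() or (plates["plated_fraction"] > 1).any():
        raise ValueError("plated_fraction must lie in (0, 1]")
    if (plates["colonies"] < 0).any():
        raise ValueError("colony counts must be non-negative")
    grouped = plates.groupby("plate_class")
    frac = grouped["plated_fraction"].sum()
    if (frac <= 0).any():
        raise ValueError("zero total plated fraction for some plate class")
    return grouped["colonies"].sum() / frac


def percent_double_posttransform(n_a: float, n_b: float, n_ab: float) -> float:
    """Percent double transformants directly after transformation.

    2 nAB / (nA + nB - nAB) * 100; the denominator is the total number of
    transformants (doubles appear on both single-dropout plates and are
    subtracted once).
    """
    denom = n_a + n_b - n_ab
    if denom <= 0:
        raise ValueError("total transformant count (nA + nB - nAB) must be positive")
    return 200.0 * n_ab / denom


def percent_double_postselection(n_a: float, n_ab: float) -> float:
    """Percent double transformants after the selection rounds.

    2 nAB / (nA - nAB) * 100; only the ura marker is selected, so the -leu
    plating drops out of the formula.
    """
    denom = n_a - n_ab
    if denom <= 0:
        raise ValueError("nA - nAB must be positive")
    return 200.0 * n_ab / denom


def summarize_replicates(estimates) -> tuple[float, float]:
    """Mean and sample standard deviation over replicate estimates;
    sd is NaN (flagged undefined) for a single replicate."""
    vals = np.asarray(
        [e.percent_double if isinstance(e, DoubleTransformantEstimate) else e for e in estimates],
        dtype=float,
    )
    if len(vals) == 0:
        raise ValueError("at least one replicate is required")
    sd = float(vals.std(ddof=1)) if len(vals) > 1 else float("nan")
    return float(vals.mean()), sd


def read_plates_csv(path) -> pd.DataFrame:
    """Read a colony-count CSV with columns plate_class, colonies, volume_ul,
    dilution, culture_ml, replicate and derive the plated culture fraction.

    ``dilution`` is the dilution factor of the plated aliquot as a fraction
    (1 for undiluted, 0.01 for a 1/100 dilution).
    """
    df = pd.read_csv(path)
    needed = {"plate_class", "colonies", "volume_ul", "dilution", "culture_ml"}
    if not needed <= set(df.columns):
        raise ValueError(f"plates CSV needs columns {sorted(needed)}")
    df["plated_fraction"] = df["volume_ul"] * 1e-3 * df["dilution"] / df["culture_ml"]
    if "replicate" not in df.columns:
        df["replicate"] = 1
    return df


class DoubleTransformantModel:
    """Estimate the multi-plasmid cell fraction from plating replicates.

    ``stage`` selects the estimator: 'post_transform' uses all three plate
    classes, 'post_selection' only -ura and -ura-leu.
    """

    def __init__(self, plates: pd.DataFrame, stage: str = "post_transform"):
        if stage not in ("post_transform", "post_selection"):
            raise ValueError("stage must be 'post_transform' or 'post_selection'")
        self.plates = plates
        self.stage = stage

    @classmethod
    def from_csv(cls, path, stage: str = "post_transform") -> "DoubleTransformantModel":
        return cls(read_plates_csv(path), stage)

    def fit(self) -> "DoubleTransformantResults":
        per_rep = []
        reps = self.plates["replicate"].unique() if "replicate" in self.plates else [1]
        for rep in reps:
            sub = (
                self.plates[self.plates["replicate"] == rep]
                if "replicate" in self.plates
                else self.plates
            )
            culture = scale_to_culture(sub)
            n_ab = culture.get("sel_AB", 0.0)
            n_a = culture.get("sel_A")
            if n_a is None:
                raise ValueError("missing sel_A (-ura) plates")
            if self.stage == "post_transform":
                n_b = culture.get("sel_B")
                if n_b is None:
                    raise ValueError("missing sel_B (-leu) plates for post_transform stage")
                pct = percent_double_posttransform(n_a, n_b, n_ab)
                total = n_a + n_b - n_ab
            else:
                pct = percent_double_postselection(n_a, n_ab)
                total = n_a - n_ab
            per_rep.append(
                DoubleTransformantEstimate(pct, float(total), valid=pct <= 100.0)
            )
        mean, sd = summarize_replicates(per_rep)
        return DoubleTransformantResults(self, per_rep, mean, sd)


@dataclass
class DoubleTransformantResults:
    model: DoubleTransformantModel
    replicates: list
    percent_double: float  # replicate mean
    sd: float

    def summary(self) -> str:
        lines = [
            f"Double-transformant estimate ({self.model.stage})",
            "=" * 44,
            f"replicates: {len(self.replicates)}",
            f"percent of cells with >= 2 plasmids: {self.percent_double:.3f}%"
            + ("" if np.isnan(self.sd) else f" (sd {self.sd:.3f}%)"),
        ]
        for i, e in enumerate(self.replicates, 1):
            flag = "" if e.valid else "  [INVALID > 100%]"
            lines.append(
                f"  rep {i}: {e.percent_double:.3f}%  "
                f"(total transformants {e.total_transformants:.0f}){flag}"
            )
        return "\n".join(lines)

    @staticmethod
    def expected_bias(lam: float) -> float:
        """Analytic positive bias (in %) of the post-transformation estimator
        at multiplicity lam, caused by cells with >= 3 plasmids."""
        return 100.0 * eq1_bias(lam)
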