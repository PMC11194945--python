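"""Per-variant growth rates from count tables, replicate merging and modes.

The estimator converts input/output frequency changes into growth rates in
generations per hour:

    rate = [ log2( (cOut/sum cOut) / (cIn/sum cIn) ) + log2(ODout/ODin) ] / hours

The first term is the variant's enrichment relative to the population, the
second the population's own doublings between inoculation and harvest, so
their sum is the variant's total doublings.  Rates can be negative under
sampling noise and are never clipped.

The module exposes a statsmodels-style surface: build a
:class:`CompetitionGrowthModel` from a count table plus sample metadata and
call ``fit()`` for a :class:`CompetitionGrowthResults` carrying rates,
replicate standard errors, distribution summaries and density modes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import gaussian_kde

from .counts import compute_frequencies, filter_count_table, read_counts_tsv, read_meta_tsv

__all__ = [
    "growth_rates",
    "merge_replicates",
    "modes_from_density",
    "find_modes",
    "ModeSet",
    "distribution_summary",
    "CompetitionGrowthModel",
    "CompetitionGrowthResults",
]


def growth_rates(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    input_sample: str,
    output_sample: str,
    frequencies: pd.DataFrame | None = None,
) -> pd.Series:
    """Growth rates for one input/output sample pairing (one replicate).

    ``frequencies`` may be supplied pre-computed on the *unfiltered* table so
    that the denominators describe the full population; by default they are
    computed from ``counts`` itself.
    """
    m = meta.set_index("sample_id")
    od_in = float(m.loc[output_sample, "od_in"])
    od_out = float(m.loc[output_sample, "od_out"])
    hours = float(m.loc[output_sample, "hours"])
    if hours <= 0:
        raise ValueError("growth time must be positive")
    if od_in <= 0 or od_out <= 0:
        raise ValueError("optical densities must be positive")
    freqs = compute_frequencies(counts) if frequencies is None else frequencies
    f_in = freqs[input_sample].reindex(counts.index)
    f_out = freqs[output_sample].reindex(counts.index)
    if (f_out <= 0).any():
        raise ValueError(
            "zero output frequency encountered; filter the count table "
            "(filter_count_table) before computing growth rates"
        )
    rate = (np.log2(f_out / f_in) + np.log2(od_out / od_in)) / hours
    rate.name = output_sample
    return rate


def merge_replicates(replicates: list[pd.Series]) -> pd.DataFrame:
    """Combine per-replicate rates into mean, standard error and n.

    A variant missing from some replicates (dropped by the count filter
    there) is averaged over the replicates in which it survived; ``se`` is
    the sample standard deviation over replicates divided by sqrt(n) and is
    NaN (flagged undefined) when n = 1.
    """
    if not replicates:
        raise ValueError("at least one replicate is required")
    wide = pd.concat(replicates, axis=1)
    n = wide.notna().sum(axis=1)
    rate = wide.mean(axis=1)
    se = wide.std(axis=1, ddof=1) / np.sqrt(n)
    se[n == 1] = np.nan
    out = pd.DataFrame({"rate": rate, "se": se, "n_replicates": n})
    out.index.name = "variant_id"
    return out


def modes_from_density(y) -> list[int]:
    """Indices of density values strictly greater than both neighbours.

    The neighbour-comparison rule operates on interior elements only and uses
    strict inequality, so plateaus are not modes.
    """
    y = np.asarray(y, float)
    return [
        i for i in range(1, len(y) - 1) if y[i] > y[i - 1] and y[i] > y[i + 1]
    ]


@dataclass
class ModeSet:
    """Density grid and the x-positions of its local maxima (ascending)."""

    grid_x: np.ndarray
    grid_y: np.ndarray
    modes: list[float]

    @property
    def lower(self) -> float:
        return self.modes[0]

    @property
    def upper(self) -> float:
        return self.modes[-1]


def find_modes(
    values,
    bw_method: str | float = "silverman",
    grid_points: int = 512,
    tail_bandwidths: float = 3.0,
) -> ModeSet:
    """Modes of a Gaussian kernel density of ``values``.

    The density is evaluated on an equally spaced grid spanning
    [min - k*h, max + k*h] with h the kernel bandwidth (Silverman's rule by
    default) and k = ``tail_bandwidths``; a grid point is a mode iff its
    density strictly exceeds both neighbours.
    """
    values = np.asarray(values, float)
    values = values[np.isfinite(values)]
    if len(values) < 2:
        raise ValueError("at least two finite values are required")
    if np.ptp(values) == 0:
        raise ValueError("values are constant; density has no well-defined modes")
    kde = gaussian_kde(values, bw_method=bw_method)
    h = kde.factor * values.std(ddof=1)
    x = np.linspace(values.min() - tail_bandwidths * h, values.max() + tail_bandwidths * h, grid_points)
    y = kde(x)
    idx = modes_from_density(y)
    return ModeSet(x, y, [float(x[i]) for i in idx])


def distribution_summary(rates, **mode_kwargs) -> dict:
    """Quartiles, IQR, sd and lower/upper density modes of a rate vector."""
    rates = np.asarray(rates, float)
    rates = rates[np.isfinite(rates)]
    if len(rates) < 2:
        raise ValueError("at least two rates are required")
    q1, med, q3 = np.percentile(rates, [25, 50, 75])
    out = {
        "n": int(len(rates)),
        "mean": float(rates.mean()),
        "sd": float(rates.std(ddof=1)),
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "iqr": float(q3 - q1),
    }
    try:
        ms = find_modes(rates, **mode_kwargs)
        out["lower_mode"] = ms.lower
        out["upper_mode"] = ms.upper
        out["n_modes"] = len(ms.modes)
    except ValueError:
        out["lower_mode"] = out["upper_mode"] = np.nan
        out["n_modes"] = 0
    return out


class CompetitionGrowthModel:
    """Growth-rate model for one pooled competition experiment.

    Parameters
    ----------
    counts : full (unfiltered) variant-level count table, variants x samples.
    meta : sample metadata with sample_id, role, replicate, condition,
        od_in, od_out, hours.
    min_input, min_output : count-filter thresholds applied at fit time.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        meta: pd.DataFrame,
        min_input: int = 10,
        min_output: int = 1,
    ):
        missing = set(meta["sample_id"]) - set(counts.columns)
        if missing:
            raise ValueError(f"metadata samples missing from count table: {sorted(missing)}")
        self.counts = counts
        self.meta = meta
        self.min_input = min_input
        self.min_output = min_output

    @classmethod
    def from_tsv(cls, counts_path, meta_path, **kwargs) -> "CompetitionGrowthModel":
        return cls(read_counts_tsv(counts_path), read_meta_tsv(meta_path), **kwargs)

    @classmethod
    def from_simulation(cls, assay, **kwargs) -> "CompetitionGrowthModel":
        return cls(assay.counts, assay.meta, **kwargs)

    def _pairings(self) -> list[tuple[str, int, str, str]]:
        """(condition, replicate, input_sample, output_sample) tuples."""
        out = []
        for (cond, rep), grp in self.meta.groupby(["condition", "replicate"], sort=False):
            ins = grp.loc[grp["role"] == "input", "sample_id"].tolist()
            outs = grp.loc[grp["role"] == "output", "sample_id"].tolist()
            if len(ins) != 1 or len(outs) != 1:
                raise ValueError(
                    f"condition {cond!r} replicate {rep} must have exactly one "
                    f"input and one output sample (got {len(ins)}/{len(outs)})"
                )
            out.append((cond, rep, ins[0], outs[0]))
        return out

    def fit(self) -> "CompetitionGrowthResults":
        frequencies = compute_frequencies(self.counts)  # before filtering
        filtered, dropped = filter_count_table(
            self.counts, self.meta, self.min_input, self.min_output
        )
        per_condition: dict[str, list[pd.Series]] = {}
        for cond, rep, in_s, out_s in self._pairings():
            r = growth_rates(filtered, self.meta, in_s, out_s, frequencies=frequencies)
            per_condition.setdefault(cond, []).append(r)
        tables = []
        replicate_rates = {}
        for cond, reps in per_condition.items():
            merged = merge_replicates(reps)
            merged.insert(0, "condition", cond)
            tables.append(merged)
            replicate_rates[cond] = pd.concat(reps, axis=1)
        growth_table = pd.concat(tables)
        return CompetitionGrowthResults(self, growth_table, replicate_rates, dropped)


@dataclass
class CompetitionGrowthResults:
    """Fitted growth rates with replicate uncertainty and diagnostics."""

    model: CompetitionGrowthModel
    growth_table: pd.DataFrame  # index variant_id; condition, rate, se, n_replicates
    replicate_rates: dict  # condition -> variants x replicates DataFrame
    dropped: pd.DataFrame  # variant_id, reason

    @property
    def conditions(self) -> list[str]:
        return list(self.replicate_rates)

    def _condition(self, condition: str | None) -> str:
        conds = self.conditions
        if condition is None:
            if len(conds) != 1:
                raise ValueError(f"specify a condition among {conds}")
            return conds[0]
        if condition not in conds:
            raise KeyError(f"unknown condition {condition!r}; have {conds}")
        return condition

    def rates(self, condition: str | None = None) -> pd.Series:
        cond = self._condition(condition)
        sub = self.growth_table[self.growth_table["condition"] == cond]
        return sub["rate"]

    def modes(self, condition: str | None = None, **kwargs) -> ModeSet:
        return find_modes(self.rates(condition), **kwargs)

    def distribution(self, condition: str | None = None) -> dict:
        return distribution_summary(self.rates(condition))

    def summary(self) -> str:
        lines = [
            "Competition growth-rate estimates",
            "=" * 46,
            f"variants in counts: {len(self.model.counts):>6d}    "
            f"dropped by filter: {len(self.dropped)}",
            f"filter: >= {self.model.min_input} reads in every input, "
            f">= {self.model.min_output} in every output",
            "-" * 46,
        ]
        for cond in self.conditions:
            d = distribution_summary(self.rates(cond))
            lines.append(
                f"condition {cond!r}: n={d['n']}  mean={d['mean']:.4f}  "
                f"sd={d['sd']:.4f}  IQR={d['iqr']:.4f}"
            )
            if d["n_modes"]:
                lines.append(
                    f"    modes (gen/h): lower={d['lower_mode']:.4f}  "
                    f"upper={d['upper_mode']:.4f}  (k={d['n_modes']})"
                )
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.growth_table.to_csv(path, sep="\t", index_label="variant_id")

    def plot_distribution(self, condition: str | None = None, ax=None):
        """Kernel-density plot of the growth-rate distribution with modes."""
        import matplotlib.pyplot as plt

        ms = self.modes(condition)
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(ms.grid_x, ms.grid_y)
        for m in ms.modes:
            ax.axvline(m, ls="--", lw=0.8, color="grey")
        ax.set_xlabel("growth rate (generations/hour)")
        ax.set_ylabel("density")
        return ax
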