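"""Forward simulation of the pooled competitive-growth assay.

The generative model, stage by stage:

1. **Transformation** — each founder cell takes up m ~ zero-truncated
   Poisson(lambda) plasmids drawn i.i.d. from the library pool; lambda is
   proportional to the DNA mass transformed.
2. **Lag phase** — for the first ``t_lag`` hours in methotrexate every cell
   grows at a common rate ``r_lag`` on stored metabolites, regardless of the
   interaction it carries.
3. **Selection** — afterwards each clone grows exponentially at the maximum
   rate over its plasmids (a cell carrying a strong and a weak pair grows
   like the strong one).
4. **Harvest** — the culture is harvested when the population has doubled
   ``g_target`` times (an optical-density trigger), which fixes the elapsed
   time T implicitly.
5. **Sequencing** — input and output samples are read at a fixed depth,
   multinomially in stochastic mode or as exact expectations in
   expected-value mode; each plasmid copy in a cell contributes an equal
   share of the cell's read weight.

Two harvest protocols are supported: ``standard`` takes the input sample
before methotrexate exposure so the recorded growth time includes the lag,
and ``pre_incubation`` takes it after ``t_lag`` hours in methotrexate and
inoculates a fresh culture, which removes the lag from the recorded time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .library import (
    BALANCED_PARTNERS,
    JUN_ZIPPER,
    PARTNER_DG,
    BarcodeMap,
    LibrarySpec,
    assign_barcodes,
    enumerate_single_substitutions,
    sample_interaction_energies,
)
from .thermo import ThermoModel, fraction_bound, growth_rate_from_binding
from .ztp import sample_ztp

__all__ = [
    "AssayConfig",
    "FounderClone",
    "ClonePool",
    "SimulatedAssay",
    "build_truth",
    "simulate_transformation",
    "clone_growth_rate",
    "solve_harvest_time",
    "simulate_competition",
    "sample_reads",
    "simulate_assay",
    "simulate_double_transformant_plating",
    "write_fastq",
]

PLATE_CLASSES = ("sel_A", "sel_B", "sel_AB")


class NoHarvestError(RuntimeError):
    """The culture can never reach the target number of generations."""


@dataclass(frozen=True)
class AssayConfig:
    """Experimental knobs of one competition assay.

    lambda_plasmids : mean plasmid multiplicity per transformed cell
        (proportional to DNA mass; ~0.05 at the 1 ug operating point).
    n_founders : number of transformant cells seeding the competition.
    force_single_plasmid : bypass multiplicity sampling (every cell gets
        exactly one plasmid; the lambda -> 0 limit).
    t_lag, r_lag : lag-phase duration (h) and common lag growth rate
        (generations/h).
    g_target : population doublings at harvest (OD-triggered).
    od_in, od_out : optical densities at inoculation and harvest;
        od_out defaults to od_in * 2**g_target.
    depth_in, depth_out : sequencing reads per input/output sample.
    n_replicates : independent transformations + competitions.
    loss_rate : per-generation plasmid-loss probability (crude knob,
        default 0; each extra copy is retained w.p. (1-loss)**g_target).
    mtx_dose : methotrexate concentration as a multiple of 1X (200 ug/mL).
    multi_penalty : multiplicative factor on the dominant rate of clones
        carrying >= 2 distinct plasmids (default 1.0 = pure dominance).
    protocol : 'standard' or 'pre_incubation' (see module docstring).
    mode : 'stochastic' or 'expected' read sampling.
    condition : free-text label recorded in the sample metadata.
    seed : top-level seed; all sub-streams are derived from it.
    """

    lambda_plasmids: float = 0.05
    n_founders: int = 200_000
    force_single_plasmid: bool = False
    t_lag: float = 2.5
    r_lag: float = 0.23
    g_target: float = 5.0
    od_in: float = 0.05
    od_out: float | None = None
    depth_in: int = 1_000_000
    depth_out: int = 1_000_000
    n_replicates: int = 1
    loss_rate: float = 0.0
    mtx_dose: float = 1.0
    multi_penalty: float = 1.0
    protocol: str = "standard"
    mode: str = "stochastic"
    condition: str = "default"
    seed: int = 0

    def __post_init__(self):
        if self.lambda_plasmids <= 0:
            raise ValueError("lambda_plasmids must be positive")
        if self.t_lag < 0 or self.r_lag < 0:
            raise ValueError("t_lag and r_lag must be non-negative")
        if self.g_target <= 0:
            raise ValueError("g_target must be positive")
        if self.depth_in <= 0 or self.depth_out <= 0:
            raise ValueError("sequencing depths must be positive")
        if self.protocol not in ("standard", "pre_incubation"):
            raise ValueError(f"unknown protocol {self.protocol!r}")
        if self.mode not in ("stochastic", "expected"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not (0.0 <= self.loss_rate < 1.0):
            raise ValueError("loss_rate must lie in [0, 1)")
        if self.od_out is not None:
            ratio = self.od_out / self.od_in
            if abs(np.log2(ratio) - self.g_target) > 0.1:
                raise ValueError(
                    "od_out/od_in must equal 2**g_target up to rounding "
                    f"(got ratio {ratio:.4g} for g_target={self.g_target})"
                )

    @property
    def effective_od_out(self) -> float:
        return self.od_out if self.od_out is not None else self.od_in * 2.0**self.g_target


@dataclass
class FounderClone:
    """One transformant cell lineage: its plasmid multiset and abundance."""

    plasmids: dict  # variant_id -> copy count
    abundance: float = 1.0

    def __post_init__(self):
        if not self.plasmids or sum(self.plasmids.values()) < 1:
            raise ValueError("a founder clone must carry at least one plasmid")
        if self.abundance < 0:
            raise ValueError("abundance must be non-negative")

    @property
    def multiplicity(self) -> int:
        return int(sum(self.plasmids.values()))


class ClonePool:
    """Array-backed collection of founder clones (sequence of FounderClone).

    ``plasmid_idx`` holds the flat plasmid draws (indices into
    ``variant_ids``), segmented per clone by ``starts``.
    """

    def __init__(self, variant_ids: Sequence[str], plasmid_idx: np.ndarray,
                 multiplicities: np.ndarray, abundance: np.ndarray | None = None):
        self.variant_ids = list(variant_ids)
        self.plasmid_idx = np.asarray(plasmid_idx, dtype=np.int64)
        self.multiplicities = np.asarray(multiplicities, dtype=np.int64)
        if np.any(self.multiplicities < 1):
            raise ValueError("every clone must carry at least one plasmid")
        self.starts = np.concatenate(([0], np.cumsum(self.multiplicities)[:-1]))
        if self.multiplicities.sum() != len(self.plasmid_idx):
            raise ValueError("plasmid_idx length does not match multiplicities")
        self.abundance = (
            np.ones(len(self.multiplicities)) if abundance is None else np.asarray(abundance, float)
        )

    def __len__(self) -> int:
        return len(self.multiplicities)

    def __getitem__(self, i: int) -> FounderClone:
        s, m = self.starts[i], self.multiplicities[i]
        ids, counts = np.unique(self.plasmid_idx[s : s + m], return_counts=True)
        return FounderClone(
            {self.variant_ids[j]: int(c) for j, c in zip(ids, counts)},
            float(self.abundance[i]),
        )

    def multi_plasmid_fraction(self) -> float:
        return float(np.mean(self.multiplicities >= 2))

    def clone_rates(self, rates: np.ndarray, multi_penalty: float = 1.0) -> np.ndarray:
        """Per-clone growth rate: max over member plasmids (dominance),
        optionally penalised for clones with >= 2 plasmids."""
        r = np.maximum.reduceat(np.asarray(rates, float)[self.plasmid_idx], self.starts)
        if multi_penalty != 1.0:
            r = np.where(self.multiplicities >= 2, r * multi_penalty, r)
        return r

    def variant_read_weights(self, abundance: np.ndarray | None = None) -> np.ndarray:
        """Per-variant read weight: each plasmid copy contributes an equal
        share abundance/m of its clone's weight."""
        a = self.abundance if abundance is None else np.asarray(abundance, float)
        share = np.repeat(a / self.multiplicities, self.multiplicities)
        w = np.zeros(len(self.variant_ids))
        np.add.at(w, self.plasmid_idx, share)
        return w


def build_truth(
    partners: Sequence[str] = BALANCED_PARTNERS,
    thermo: ThermoModel | None = None,
    dose: float = 1.0,
    wt_sequence: str = JUN_ZIPPER,
    partner_dg: Mapping[str, float] | None = None,
    effect_mean: float = 1.0,
    effect_sd: float = 1.0,
    include_wt: bool = True,
    seed: int = 0,
) -> pd.DataFrame:
    """Ground-truth table for a library: one row per (prey variant, partner)
    with its binding free energy and the growth rate implied by the
    thermodynamic map at the given methotrexate dose.

    Columns: variant_id, prey, partner, dg, true_rate.
    """
    thermo = thermo or ThermoModel()
    dg0 = {p: (partner_dg or PARTNER_DG)[p] for p in partners}
    variants = enumerate_single_substitutions(wt_sequence, include_wt=include_wt)
    truth = sample_interaction_energies(
        variants, dg0, effect_mean=effect_mean, effect_sd=effect_sd, seed=seed
    )
    truth["true_rate"] = growth_rate_from_binding(
        fraction_bound(truth["dg"].to_numpy(), thermo), dose, thermo
    )
    return truth


def simulate_transformation(
    pool_frequencies: pd.Series | np.ndarray,
    config: AssayConfig,
    rng: np.random.Generator | None = None,
    variant_ids: Sequence[str] | None = None,
) -> ClonePool:
    """Transform ``n_founders`` cells from a plasmid pool.

    Each founder draws a multiplicity m ~ ZTP(lambda) (or m = 1 with
    ``force_single_plasmid``) and m plasmids i.i.d. from the pool
    frequencies; every founder starts at abundance 1.
    """
    if isinstance(pool_frequencies, pd.Series):
        variant_ids = list(pool_frequencies.index)
        freqs = pool_frequencies.to_numpy(dtype=float)
    else:
        freqs = np.asarray(pool_frequencies, dtype=float)
        if variant_ids is None:
            variant_ids = [str(i) for i in range(len(freqs))]
    if not np.isclose(freqs.sum(), 1.0):
        raise ValueError("pool frequencies must sum to 1")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = config.n_founders
    if config.force_single_plasmid:
        m = np.ones(n, dtype=np.int64)
    else:
        m = sample_ztp(config.lambda_plasmids, n, rng)
    flat = rng.choice(len(freqs), size=int(m.sum()), p=freqs)
    return ClonePool(variant_ids, flat, m)


def clone_growth_rate(
    clone: FounderClone, rates: Mapping[str, float], multi_penalty: float = 1.0
) -> float:
    """Growth rate of one clone: the maximum over its plasmids' rates
    (the strong interaction pair dominates), optionally penalised when the
    clone carries two or more plasmids."""
    missing = [v for v in clone.plasmids if v not in rates]
    if missing:
        raise KeyError(f"no growth rate defined for plasmids {missing}")
    r = max(rates[v] for v in clone.plasmids)
    if clone.multiplicity >= 2 and multi_penalty != 1.0:
        r *= multi_penalty
    return float(r)


def solve_harvest_time(
    abundances: np.ndarray, rates: np.ndarray, config: AssayConfig, tol: float = 1e-10
) -> float:
    """Elapsed time T at which the population has doubled ``g_target`` times.

    Solves  sum_c a_c 2^(r_lag t_lag + r_c (T - t_lag)) = 2^G sum_c a_c  by
    bisection to absolute tolerance ``tol`` on T.  If the lag alone already
    produces G doublings the harvest happens inside the lag at T = G/r_lag.
    """
    a = np.asarray(abundances, float)
    r = np.asarray(rates, float)
    if np.any(a < 0) or a.sum() <= 0:
        raise ValueError("abundances must be non-negative with positive total")
    G, t_lag, r_lag = config.g_target, config.t_lag, config.r_lag
    if r_lag * t_lag >= G:
        return G / r_lag
    if np.all(r <= 0):
        raise NoHarvestError(
            "all growth rates are zero and the lag phase cannot reach g_target"
        )
    total = a.sum()

    def excess(T: float) -> float:
        return np.sum(a * 2.0 ** (r_lag * t_lag + r * (T - t_lag))) - 2.0**G * total

    lo = t_lag
    hi = t_lag + (G - r_lag * t_lag) / r[r > 0].max()  # fastest clone alone is not enough
    while excess(hi) < 0:
        hi = t_lag + 2 * (hi - t_lag)
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if excess(mid) < 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def simulate_competition(
    abundances: np.ndarray, rates: np.ndarray, config: AssayConfig
) -> tuple[np.ndarray, float]:
    """Grow clones to the OD-triggered harvest.

    Returns per-clone harvest abundances and the elapsed competition time
    recorded in the metadata.  Under the ``pre_incubation`` protocol the lag
    happens before the input sample is taken, so growth is lag-free and the
    recorded time excludes the lag; uniform lag growth does not change the
    input frequencies.
    """
    a = np.asarray(abundances, float)
    r = np.asarray(rates, float)
    if config.protocol == "pre_incubation":
        cfg = replace(config, t_lag=0.0)
        T = solve_harvest_time(a, r, cfg)
        return a * 2.0 ** (r * T), T
    T = solve_harvest_time(a, r, config)
    t_eff = min(T, config.t_lag)  # harvest can fall inside the lag
    out = a * 2.0 ** (config.r_lag * t_eff + r * np.maximum(T - config.t_lag, 0.0))
    return out, T


def sample_reads(
    weights: np.ndarray, depth: int, mode: str, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Sequencing counts from per-variant read weights.

    stochastic: one multinomial(depth, w/sum w) draw; expected: exact
    expectations depth * w/sum w (real-valued).  Counts sum to depth.
    """
    w = np.asarray(weights, float)
    if np.any(w < 0):
        raise ValueError("read weights must be non-negative")
    total = w.sum()
    if total <= 0:
        raise ValueError("total read weight is zero")
    p = w / total
    if mode == "expected":
        return depth * p
    if mode == "stochastic":
        rng = rng if rng is not None else np.random.default_rng()
        return rng.multinomial(depth, p).astype(float)
    raise ValueError(f"unknown mode {mode!r}")


@dataclass
class SimulatedAssay:
    """Counts, metadata and ground truth of one simulated experiment."""

    counts: pd.DataFrame  # variants x samples
    meta: pd.DataFrame  # sample_id, role, replicate, condition, od_in, od_out, hours
    truth: pd.DataFrame  # variant_id, true_rate (+ dg where applicable)
    elapsed: dict  # replicate -> competition hours
    config: AssayConfig

    def to_dir(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.counts.to_csv(outdir / "counts.tsv", sep="\t", index_label="variant_id")
        self.meta.to_csv(outdir / "meta.tsv", sep="\t", index=False)
        self.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)


def _apply_plasmid_loss(pool: ClonePool, config: AssayConfig, rng) -> ClonePool:
    """Crude plasmid-loss knob: each copy beyond a guaranteed one is retained
    with probability (1 - loss_rate) ** g_target."""
    keep_p = (1.0 - config.loss_rate) ** config.g_target
    keep = rng.random(len(pool.plasmid_idx)) < keep_p
    # always retain the first copy of each clone
    keep[pool.starts] = True
    new_m = np.add.reduceat(keep.astype(np.int64), pool.starts)
    return ClonePool(pool.variant_ids, pool.plasmid_idx[keep], new_m, pool.abundance)


def simulate_assay(
    truth: pd.DataFrame,
    config: AssayConfig,
    pool_frequencies: pd.Series | None = None,
) -> SimulatedAssay:
    """Run the full forward model for ``config.n_replicates`` replicates.

    ``truth`` must carry ``variant_id`` and ``true_rate`` columns (see
    :func:`build_truth`); ``pool_frequencies`` defaults to a uniform plasmid
    pool over the truth table's variants.
    """
    variant_ids = list(truth["variant_id"])
    rates = truth["true_rate"].to_numpy(dtype=float)
    if pool_frequencies is None:
        pool = pd.Series(np.full(len(variant_ids), 1.0 / len(variant_ids)), index=variant_ids)
    else:
        pool = pool_frequencies.reindex(variant_ids).fillna(0.0)
        pool = pool / pool.sum()

    seed_seq = np.random.SeedSequence(config.seed)
    columns: dict[str, np.ndarray] = {}
    meta_rows = []
    elapsed = {}
    for rep in range(1, config.n_replicates + 1):
        rng = np.random.default_rng(seed_seq.spawn(1)[0])
        if config.force_single_plasmid and config.mode == "expected":
            # fully deterministic path: variants are the clones
            w_in = pool.to_numpy()
            out, T = simulate_competition(w_in, rates, config)
            w_out = out
        else:
            cpool = simulate_transformation(pool, config, rng=rng)
            if config.loss_rate > 0:
                cpool = _apply_plasmid_loss(cpool, config, rng)
            w_in = cpool.variant_read_weights()
            crates = cpool.clone_rates(rates, config.multi_penalty)
            out_ab, T = simulate_competition(cpool.abundance, crates, config)
            w_out = cpool.variant_read_weights(out_ab)
        columns[f"input_rep{rep}"] = sample_reads(w_in, config.depth_in, config.mode, rng)
        columns[f"output_rep{rep}"] = sample_reads(w_out, config.depth_out, config.mode, rng)
        elapsed[rep] = T
        for role, depth in (("input", config.depth_in), ("output", config.depth_out)):
            meta_rows.append(
                {
                    "sample_id": f"{role}_rep{rep}",
                    "role": role,
                    "replicate": rep,
                    "condition": config.condition,
                    "od_in": config.od_in,
                    "od_out": config.effective_od_out,
                    "hours": T,
                }
            )
    counts = pd.DataFrame(columns, index=pd.Index(variant_ids, name="variant_id"))
    return SimulatedAssay(counts, pd.DataFrame(meta_rows), truth.copy(), elapsed, config)


def simulate_double_transformant_plating(
    lam: float,
    n_cells: int,
    plating_fractions: Mapping[str, Sequence[float]] | float = 1.0,
    seed: int = 0,
    force_multiplicity: int | None = None,
) -> pd.DataFrame:
    """Two-marker plating experiment for counting double transformants.

    ``n_cells`` transformed cells draw m ~ ZTP(lam) plasmids from an
    equimolar two-marker (ura/leu) pool; a cell forms a colony on -ura iff it
    carries >= 1 ura plasmid, on -leu iff >= 1 leu plasmid and on -ura-leu
    iff both.  Plate counts are binomially thinned by the plated culture
    fraction.  ``force_multiplicity`` fixes m for every cell (e.g. 2 to
    realise the 25/50/25 marker composition exactly).

    Returns a ColonyCounts frame: plate_class in {sel_A, sel_B, sel_AB},
    colonies, plated_fraction.
    """
    rng = np.random.default_rng(seed)
    if force_multiplicity is not None:
        m = np.full(n_cells, int(force_multiplicity), dtype=np.int64)
    else:
        m = sample_ztp(lam, n_cells, rng)
    k_ura = rng.binomial(m, 0.5)
    k_leu = m - k_ura
    n_class = {
        "sel_A": int(np.sum(k_ura >= 1)),
        "sel_B": int(np.sum(k_leu >= 1)),
        "sel_AB": int(np.sum((k_ura >= 1) & (k_leu >= 1))),
    }
    if isinstance(plating_fractions, (int, float)):
        plating_fractions = {c: [float(plating_fractions)] for c in PLATE_CLASSES}
    rows = []
    for cls in PLATE_CLASSES:
        for frac in plating_fractions.get(cls, []):
            if not (0.0 < frac <= 1.0):
                raise ValueError(f"plated fraction must lie in (0, 1], got {frac}")
            colonies = (
                n_class[cls] if frac == 1.0 else int(rng.binomial(n_class[cls], frac))
            )
            rows.append({"plate_class": cls, "colonies": colonies, "plated_fraction": frac})
    return pd.DataFrame(rows)


def write_fastq(
    counts: pd.Series,
    barcode_map: BarcodeMap,
    path,
    constant: str = "GGATCC",
    qual_char: str = "I",
) -> int:
    """Write error-free single-end reads for one sample's variant counts.

    Read layout (a documented convention of this package): positions 0-24
    prey barcode, 24-44 bait barcode, then a constant spacer filling the read
    to 50 bp.  A variant's counts are split as evenly as possible across its
    barcode pairs.  Counts are rounded to integers.  Returns reads written.
    """
    path = Path(path)
    n_written = 0
    with open(path, "w") as fh:
        for variant_id, count in counts.items():
            count = int(round(count))
            if count <= 0:
                continue
            bcs = barcode_map.barcodes_of(variant_id)
            if bcs.empty:
                raise KeyError(f"variant {variant_id!r} has no barcodes in the map")
            base, extra = divmod(count, len(bcs))
            for j, (_, row) in enumerate(bcs.iterrows()):
                n_reads = base + (1 if j < extra else 0)
                seq = row["barcode_prey"] + row["barcode_bait"] + constant
                qual = qual_char * len(seq)
                for k in range(n_reads):
                    fh.write(f"@{variant_id}|{j}|{k}\n{seq}\n+\n{qual}\n")
                n_written += n_reads
    return n_written
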