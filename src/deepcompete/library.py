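"""Variant libraries: substitution enumeration, barcodes, interaction energies.

A library pairs every single amino-acid substitution of a prey domain (plus
the wild type) with a small panel of bait partners.  Each prey variant gets
one or more random 24 bp molecular barcodes and each bait partner a 20 bp
barcode; the juxtaposed pair identifies the expressed protein pair in
sequencing reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AA_ALPHABET",
    "JUN_ZIPPER",
    "PARTNER_DG",
    "BALANCED_PARTNERS",
    "SLOW_PARTNERS",
    "FAST_PARTNERS",
    "LibrarySpec",
    "BarcodeMap",
    "enumerate_single_substitutions",
    "assign_barcodes",
    "sample_interaction_energies",
]

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: 32-residue segment of the human JUN leucine zipper used as the default
#: prey domain (608 = 19 x 32 single substitutions).
JUN_ZIPPER = "RIARLEEKVKTLKAQNSELASTANMLREQVAQ"

#: Default partner-level baseline binding free energies (kcal/mol) for the
#: bZIP panel, spanning non-interactor to strongest interactor.  These are
#: illustrative simulator defaults on the model's energy scale, not measured
#: values.
PARTNER_DG = {
    "JDP2": -4.0,  # strongest interactor
    "FOS": -3.0,   # strong interactor
    "ATF7": 0.0,   # medium/weak interactor
    "ATF2": 1.0,   # weak interactor
    "NFE2": 2.0,   # non-interactor
}

BALANCED_PARTNERS = ("FOS", "ATF7", "NFE2")
SLOW_PARTNERS = ("ATF2", "ATF7", "NFE2")
FAST_PARTNERS = ("FOS", "ATF7", "JDP2")

WT_LABEL = "WT"


class NonStandardResidueError(ValueError):
    """Raised when a sequence contains a letter outside the 20-residue alphabet."""


@dataclass(frozen=True)
class LibrarySpec:
    """Shape of a barcoded prey-by-bait library."""

    wt_sequence: str = JUN_ZIPPER
    partners: tuple = BALANCED_PARTNERS
    barcodes_per_variant: int = 1
    barcode_lengths: tuple = (24, 20)  # (prey bp, bait bp)

    def __post_init__(self):
        _validate_sequence(self.wt_sequence)
        if self.barcodes_per_variant < 1:
            raise ValueError("barcodes_per_variant must be >= 1")
        if len(self.barcode_lengths) != 2 or any(l < 1 for l in self.barcode_lengths):
            raise ValueError("barcode_lengths must be two positive integers")


def _validate_sequence(seq: str) -> None:
    if not seq:
        raise NonStandardResidueError("empty sequence")
    bad = set(seq) - set(AA_ALPHABET)
    if bad:
        raise NonStandardResidueError(f"non-standard residues in sequence: {sorted(bad)}")


def enumerate_single_substitutions(wt_sequence: str, include_wt: bool = False) -> list[str]:
    """All length-preserving single-residue substitutions of ``wt_sequence``.

    Labels follow the field convention ``<wt><1-based position><new>``
    (e.g. ``R1A``); 19 substitutions per position, none duplicating the wild
    type.  With ``include_wt`` the wild type is prepended under the label
    ``WT``.
    """
    _validate_sequence(wt_sequence)
    labels = [
        f"{wt}{i + 1}{aa}"
        for i, wt in enumerate(wt_sequence)
        for aa in AA_ALPHABET
        if aa != wt
    ]
    if include_wt:
        return [WT_LABEL] + labels
    return labels


@dataclass
class BarcodeMap:
    """Injective map from (prey barcode, bait barcode) to variant-pair id."""

    table: pd.DataFrame  # columns: barcode_prey, barcode_bait, variant_id

    def __post_init__(self):
        pairs = self.table[["barcode_prey", "barcode_bait"]]
        if pairs.duplicated().any():
            raise ValueError("barcode map is not injective: duplicate barcode pairs")

    def __len__(self) -> int:
        return len(self.table)

    def lookup(self) -> dict:
        """dict (prey_bc, bait_bc) -> variant_id for fast read matching."""
        return {
            (p, b): v
            for p, b, v in zip(
                self.table["barcode_prey"], self.table["barcode_bait"], self.table["variant_id"]
            )
        }

    def barcodes_of(self, variant_id: str) -> pd.DataFrame:
        return self.table[self.table["variant_id"] == variant_id]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "BarcodeMap":
        return cls(pd.read_csv(path, sep="\t", dtype=str))


def _random_kmers(n: int, length: int, rng: np.random.Generator) -> list[str]:
    """``n`` distinct random DNA k-mers, resampling on collision."""
    if n > 4**length:
        raise ValueError(
            f"cannot draw {n} distinct barcodes of length {length} (only {4 ** length} exist)"
        )
    bases = np.array(list("ACGT"))
    seen: set[str] = set()
    out: list[str] = []
    while len(out) < n:
        draw = ["".join(row) for row in bases[rng.integers(0, 4, size=(n - len(out), length))]]
        for kmer in draw:
            if kmer not in seen:
                seen.add(kmer)
                out.append(kmer)
    return out


def assign_barcodes(variants, partners, spec: LibrarySpec, seed: int) -> BarcodeMap:
    """Draw random molecular barcodes for every (prey variant, bait partner).

    Each prey variant receives ``spec.barcodes_per_variant`` distinct prey
    barcodes and each bait partner one bait barcode; every combination is one
    row of the map.  Deterministic given ``seed``.
    """
    rng = np.random.default_rng(seed)
    prey_len, bait_len = spec.barcode_lengths
    n_prey = len(variants) * spec.barcodes_per_variant
    prey_bcs = _random_kmers(n_prey, prey_len, rng)
    bait_bcs = _random_kmers(len(partners), bait_len, rng)
    rows = []
    i = 0
    for v in variants:
        for _ in range(spec.barcodes_per_variant):
            pbc = prey_bcs[i]
            i += 1
            for partner, bbc in zip(partners, bait_bcs):
                rows.append((pbc, bbc, f"{v}:{partner}"))
    return BarcodeMap(pd.DataFrame(rows, columns=["barcode_prey", "barcode_bait", "variant_id"]))


def sample_interaction_energies(
    variants,
    partner_dg: dict,
    effect_mean: float = 1.0,
    effect_sd: float = 1.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-pair binding free energies under the additive mutation model.

    dG(v, p) = dG0_p + delta_v with a single normal perturbation delta_v per
    prey variant shared across partners (mutations act additively on the free
    energy of every complex) and delta_WT = 0.  Deterministic given ``seed``.

    Returns a DataFrame with columns variant_id, prey, partner, dg.
    """
    rng = np.random.default_rng(seed)
    deltas = {
        v: 0.0 if v == WT_LABEL else rng.normal(effect_mean, effect_sd) for v in variants
    }
    rows = [
        (f"{v}:{p}", v, p, dg0 + deltas[v])
        for v in variants
        for p, dg0 in partner_dg.items()
    ]
    return pd.DataFrame(rows, columns=["variant_id", "prey", "partner", "dg"])
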