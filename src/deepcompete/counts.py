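"""From raw reads to filtered per-variant count tables.

Reads are kept only when their mean Phred quality reaches the threshold, the
constant amplicon region matches exactly and the extracted barcode pair has a
perfect (mismatch-free) match in the barcode map.  Barcode-level counts are
summed to variant level, and variants are dropped when any input sample has
fewer than ``min_input`` reads or any output sample fewer than ``min_output``.

Frequencies are always computed over the full matched variant set *before*
row filtering: they describe the sequenced population, not the analysable
subset, and are therefore stable with respect to the filter thresholds.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .library import BarcodeMap

__all__ = [
    "ReadLayout",
    "count_barcodes_from_fastq",
    "aggregate_to_variants",
    "filter_count_table",
    "compute_frequencies",
    "read_counts_tsv",
    "read_meta_tsv",
]


@dataclass(frozen=True)
class ReadLayout:
    """Coordinate windows (0-based, half-open) of the amplicon structure.

    ``constant`` optionally pins an exact spacer sequence at a window; reads
    whose constant region differs are discarded as structurally incorrect.
    """

    prey: tuple = (0, 24)
    bait: tuple = (24, 44)
    constant: tuple | None = ((44, 50), "GGATCC")

    @classmethod
    def from_yaml(cls, path) -> "ReadLayout":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        constant = raw.get("constant")
        if constant is not None:
            constant = ((constant["start"], constant["end"]), constant["sequence"])
        return cls(
            prey=(raw["prey"]["start"], raw["prey"]["end"]),
            bait=(raw["bait"]["start"], raw["bait"]["end"]),
            constant=constant,
        )


def _open_maybe_gzip(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def count_barcodes_from_fastq(
    fastq,
    barcode_map: BarcodeMap,
    layout: ReadLayout | None = None,
    min_mean_phred: float = 20.0,
    sample_id: str = "sample",
) -> tuple[pd.DataFrame, dict]:
    """Count exact barcode-pair matches in a FASTQ stream.

    A read is counted iff its mean Phred score is >= ``min_mean_phred``, its
    constant region (if the layout defines one) matches exactly, and its
    (prey, bait) barcode pair is present in the map.  Returns a barcode-level
    count table (rows: barcode pairs, one column named ``sample_id``) and a
    QC dict tallying discarded reads by reason.
    """
    layout = layout or ReadLayout()
    lut = barcode_map.lookup()
    counts: dict[tuple, int] = {}
    qc = {"n_reads": 0, "low_phred": 0, "bad_structure": 0, "unmatched": 0, "counted": 0}
    ps, pe = layout.prey
    bs, be = layout.bait
    if hasattr(fastq, "read"):
        handle = fastq
        close = False
    else:
        handle = _open_maybe_gzip(fastq)
        close = True
    try:
        for i, (title, seq, qual) in enumerate(FastqGeneralIterator(handle)):
            qc["n_reads"] += 1
            if len(qual) != len(seq):
                raise ValueError(f"malformed FASTQ record at index {i} ({title!r})")
            mean_phred = np.mean([ord(c) - 33 for c in qual])
            if mean_phred < min_mean_phred:
                qc["low_phred"] += 1
                continue
            if layout.constant is not None:
                (cs, ce), cseq = layout.constant
                if seq[cs:ce] != cseq:
                    qc["bad_structure"] += 1
                    continue
            key = (seq[ps:pe], seq[bs:be])
            if key not in lut:
                qc["unmatched"] += 1
                continue
            counts[key] = counts.get(key, 0) + 1
            qc["counted"] += 1
    finally:
        if close:
            handle.close()
    idx = pd.MultiIndex.from_tuples(
        counts.keys() or [], names=["barcode_prey", "barcode_bait"]
    )
    return pd.DataFrame({sample_id: list(counts.values())}, index=idx), qc


def aggregate_to_variants(barcode_counts: pd.DataFrame, barcode_map: BarcodeMap) -> pd.DataFrame:
    """Sum all barcodes belonging to the same variant, per sample.

    Rows of ``barcode_counts`` are (barcode_prey, barcode_bait) pairs; every
    row must be present in the map.  Per-sample totals are conserved.
    """
    lut = barcode_map.lookup()
    try:
        variant = [lut[key] for key in barcode_counts.index]
    except KeyError as err:
        raise KeyError(f"barcode pair {err.args[0]} not present in the map") from None
    out = barcode_counts.groupby(pd.Index(variant, name="variant_id")).sum()
    return out


def filter_count_table(
    counts: pd.DataFrame,
    meta: pd.DataFrame,
    min_input: int = 10,
    min_output: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop variants with < ``min_input`` reads in any input sample or
    < ``min_output`` in any output sample.

    ``meta`` must annotate every counts column with a role (input/output).
    Returns the filtered table and a report of dropped rows with reasons.
    """
    roles = meta.set_index("sample_id")["role"]
    input_cols = [c for c in counts.columns if roles.get(c) == "input"]
    output_cols = [c for c in counts.columns if roles.get(c) == "output"]
    if not input_cols or not output_cols:
        raise ValueError("count table needs at least one input and one output sample")
    in_ok = (counts[input_cols] >= min_input).all(axis=1)
    out_ok = (counts[output_cols] >= min_output).all(axis=1)
    keep = in_ok & out_ok
    reasons = np.where(
        ~in_ok & ~out_ok,
        "low_input+low_output",
        np.where(~in_ok, "low_input", "low_output"),
    )
    report = pd.DataFrame(
        {"variant_id": counts.index[~keep], "reason": reasons[~keep.to_numpy()]}
    )
    return counts[keep], report


def compute_frequencies(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-sample frequencies count / column-total.

    Must be called on the full matched table *before* filtering so that the
    denominators describe the whole sequenced population.  Every column sums
    to 1.
    """
    totals = counts.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"zero column sum in samples {bad}")
    return counts / totals


def read_counts_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="variant_id")


def read_meta_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
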