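"""Chromatin-evidence annotation of candidate variants.

Each candidate variant is intersected with peak intervals from a panel of
per-cell-line epigenomic experiments (ATAC-seq, H3K27ac ChIP-seq, DNase
hypersensitivity, TF ChIP-seq) and the per-assay-class support counts —
how many experiments of each class have a peak covering the variant — are
used to rank variants. Coordinates follow the hg convention: variants are
1-based positions, BED intervals are 0-based half-open; the conversion
lives in a single function (:func:`overlaps`).

Experiments from the same cell line count separately, mirroring the way
peak panels are reported per experiment rather than per line.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

__all__ = [
    "PeakExperiment",
    "EvidenceMatrix",
    "overlaps",
    "build_evidence",
    "rank_variants",
    "read_bed",
    "read_manifest",
]

ASSAY_CLASSES = ("ATAC", "H3K27ac", "DHS", "TF-ChIP")


@dataclass
class PeakExperiment:
    """One peak-calling experiment: assay class, cell line, and intervals."""

    experiment_id: str
    assay: str                   # ATAC, H3K27ac, DHS, or TF-ChIP
    cell_line: str
    intervals: list              # of (chrom, start, end), 0-based half-open
    tf_name: str = ""            # set for TF-ChIP experiments

    def __post_init__(self):
        for chrom, start, end in self.intervals:
            if start >= end:
                raise ValueError(
                    f"{self.experiment_id}: interval {chrom}:{start}-{end} has start >= end")
        self.intervals = merge_intervals(self.intervals)

    @property
    def assay_class(self) -> str:
        return "TF-ChIP" if self.assay.startswith("TF-ChIP") else self.assay


def merge_intervals(intervals) -> list:
    """Sort and merge overlapping/adjacent intervals per chromosome."""
    by_chrom: dict = {}
    for chrom, start, end in intervals:
        by_chrom.setdefault(chrom, []).append((int(start), int(end)))
    merged = []
    for chrom in sorted(by_chrom):
        spans = sorted(by_chrom[chrom])
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                merged.append((chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        merged.append((chrom, cur_s, cur_e))
    return merged


def overlaps(variant_chrom: str, variant_pos_1based: int, interval) -> bool:
    """Does a 1-based variant position fall inside a 0-based half-open interval?

    True iff the chromosomes match and ``start <= pos-1 < end``. A
    chromosome mismatch returns False (it is a valid negative, not an
    error).
    """
    chrom, start, end = interval
    if chrom != variant_chrom:
        return False
    return start <= variant_pos_1based - 1 < end


@dataclass
class EvidenceMatrix:
    """Variant x experiment overlap flags with per-assay support counts."""

    overlap: pd.DataFrame        # bool, variants x experiment_ids
    support: pd.DataFrame        # int, variants x assay classes
    variants: pd.DataFrame       # snp_id, chrom, pos
    tf_sites: dict               # snp_id -> sorted list of TF names bound there


def build_evidence(variants: pd.DataFrame, experiments) -> EvidenceMatrix:
    """Intersect variants with every experiment's peak set.

    Parameters
    ----------
    variants : DataFrame with columns snp_id, chrom, pos (1-based).
    experiments : iterable of PeakExperiment.

    Interval lookup uses an interval tree per experiment and chromosome;
    the result is identical to a naive all-pairs scan.
    """
    variants = variants.reset_index(drop=True)
    if len(variants) == 0:
        raise ValueError("need at least one variant")
    experiments = list(experiments)
    flags = pd.DataFrame(
        False, index=variants["snp_id"],
        columns=[e.experiment_id for e in experiments], dtype=bool)
    for exp in experiments:
        trees: dict = {}
        for chrom, start, end in exp.intervals:
            trees.setdefault(chrom, IntervalTree()).addi(start, end)
        for _, var in variants.iterrows():
            tree = trees.get(var["chrom"])
            if tree is not None and tree.overlaps_point(int(var["pos"]) - 1):
                flags.loc[var["snp_id"], exp.experiment_id] = True

    support = pd.DataFrame(0, index=flags.index, columns=list(ASSAY_CLASSES), dtype=int)
    tf_sites = {snp: set() for snp in flags.index}
    for exp in experiments:
        cls = exp.assay_class
        hit = flags[exp.experiment_id]
        support[cls] += hit.astype(int)
        if cls == "TF-ChIP" and exp.tf_name:
            for snp in flags.index[hit]:
                tf_sites[snp].add(exp.tf_name)
    return EvidenceMatrix(
        overlap=flags, support=support, variants=variants,
        tf_sites={snp: sorted(tfs) for snp, tfs in tf_sites.items()})


def rank_variants(evidence: EvidenceMatrix) -> pd.DataFrame:
    """Rank variants by chromatin support.

    Sort key: total support desc, then ATAC support desc, then TF-ChIP
    support desc, then genomic position asc (stable tie-break). The
    composite key is this package's explicit stand-in for narrative
    prioritisation and can be recomputed from the returned columns.
    """
    sup = evidence.support
    pos = evidence.variants.set_index("snp_id")["pos"]
    frame = sup.copy()
    frame["total_support"] = sup.sum(axis=1)
    frame["pos"] = pos
    frame = frame.sort_values(
        by=["total_support", "ATAC", "TF-ChIP", "pos"],
        ascending=[False, False, False, True], kind="stable")
    frame.insert(0, "rank", np.arange(1, len(frame) + 1))
    frame["tf_sites"] = [",".join(evidence.tf_sites[s]) for s in frame.index]
    return frame.reset_index()


def read_bed(path) -> list:
    """Read a BED file into (chrom, start, end) intervals.

    Raises a parse error naming the offending line number.
    """
    intervals = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            try:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            except (IndexError, ValueError) as err:
                raise ValueError(f"{path}: malformed BED line {lineno}: {line!r}") from err
            intervals.append((chrom, start, end))
    return intervals


def read_manifest(path) -> list:
    """Read an experiment manifest TSV into PeakExperiment objects.

    Columns: experiment_id, assay, cell_line, path (BED file per
    experiment); an optional tf_name column for TF-ChIP rows.
    """
    manifest = pd.read_csv(path, sep="\t")
    experiments = []
    for _, row in manifest.iterrows():
        experiments.append(PeakExperiment(
            experiment_id=str(row["experiment_id"]),
            assay=str(row["assay"]),
            cell_line=str(row["cell_line"]),
            intervals=read_bed(row["path"]),
            tf_name=str(row.get("tf_name", "") or ""),
        ))
    return experiments
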