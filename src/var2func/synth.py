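"""Seeded synthetic-data generators for every pipeline input.

Each generator emulates the statistical structure of one input the
variant-to-function pipeline consumes — two-group allele frequencies,
haplotype blocks with known population r², per-experiment peak sets with
planted overlaps, allelic sequences with a planted motif broken by one
allele, additive genotype-expression data, power-law distance-decay Hi-C
contacts with planted loops, and lognormal lipid concentration matrices
with planted class effects and missing-at-random entries.

Determinism contract: the same arguments (including the seed) always
yield byte-identical outputs. Every generator derives an independent
random stream from ``(GENERATOR_OFFSET, seed)``, so adding a new
generator never perturbs the draws of the existing ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .chromatin import PeakExperiment
from .motif import PWM

__all__ = [
    "SimConfig",
    "DEFAULT_LIPID_CLASS_SIZES",
    "gen_case_control",
    "gen_haplotype_block",
    "parse_hap_freqs",
    "population_r2",
    "gen_peak_sets",
    "gen_allelic_sequences",
    "gen_expression",
    "gen_contacts",
    "gen_lipidome",
    "write_bed",
    "write_fasta",
]

# per-generator stream offsets (see module docstring)
_STREAMS = {
    "case_control": 1, "haplotype": 2, "peaks": 3, "sequences": 4,
    "expression": 5, "contacts": 6, "lipidome": 7,
}

# 543 lipids over the nine major classes of a targeted panel; the
# glycerophospholipid total of 98 is split over its LPC/PCaa/PCae subclasses
DEFAULT_LIPID_CLASS_SIZES = {
    "AC": 40, "Cer": 38, "CE": 22, "DG": 44, "FA": 10,
    "LPC": 14, "PCaa": 49, "PCae": 35, "HexCer": 34, "SM": 15, "TG": 242,
}


def _rng(stream: str, seed: int) -> np.random.Generator:
    return np.random.default_rng([_STREAMS[stream], int(seed)])


@dataclass
class SimConfig:
    """Bundle of generator parameters for an end-to-end synthetic run.

    Defaults reproduce the study conditions of the worked scenario: the
    two-cohort case-control sample sizes and minor-allele frequencies,
    the (29 ATAC, 5 H3K27ac)-of-(30, 6) planted chromatin support, a
    10-kb-resolution contact matrix with a fivefold planted loop, and a
    543-lipid panel measured in four replicates per group.
    """

    seed: int = 0
    n_cases: int = 2101
    n_controls: int = 4202
    maf_cases: float = 0.46
    maf_controls: float = 0.41
    eqtl_beta: float = 2.0
    noise_sd: float = 1.0
    decay_alpha: float = 1.0
    n_bins: int = 200
    total_reads: int = 2_000_000
    loop_spec: tuple = ((10, 40, 5.0),)
    lipid_class_sizes: dict = field(default_factory=lambda: dict(DEFAULT_LIPID_CLASS_SIZES))
    lipid_n_per_group: int = 4
    lipid_cv: float = 0.1
    lipid_missing_rate: float = 0.02


def gen_case_control(maf_cases: float, maf_controls: float, n_cases: int,
                     n_controls: int, seed: int = 0) -> pd.DataFrame:
    """Simulate a case-control genotype/phenotype table.

    Genotypes are Binomial(2, group MAF) — Hardy-Weinberg within group —
    so the empirical MAFs converge to the targets as N grows. Age
    (uniform integer 0-10 years, the age range of the emulated pediatric
    cohort) and sex are drawn independently of genotype.

    Returns
    -------
    DataFrame with subject_id, genotype (0/1/2 minor-allele dosage),
    status (1 case / 0 control), age, sex.
    """
    for maf in (maf_cases, maf_controls):
        if not 0 < maf < 1:
            raise ValueError("MAFs must lie in (0, 1)")
    if n_cases <= 0 or n_controls <= 0:
        raise ValueError("group sizes must be positive")
    rng = _rng("case_control", seed)
    n = n_cases + n_controls
    status = np.concatenate([np.ones(n_cases, int), np.zeros(n_controls, int)])
    maf = np.where(status == 1, maf_cases, maf_controls)
    genotype = rng.binomial(2, maf)
    age = rng.integers(0, 11, size=n)
    sex = rng.integers(0, 2, size=n)
    return pd.DataFrame({
        "subject_id": [f"s{i:06d}" for i in range(n)],
        "genotype": genotype, "status": status, "age": age, "sex": sex,
    })


def parse_hap_freqs(hap_freqs: dict) -> tuple:
    """Normalise haplotype-frequency keys to 0/1 tuples.

    Keys may be 0/1 tuples or allele strings where an uppercase letter is
    the "1" allele and lowercase the "0" allele (e.g. ``"Ab" -> (1, 0)``).
    """
    parsed = {}
    n_snps = None
    for key, freq in hap_freqs.items():
        if isinstance(key, str):
            hap = tuple(1 if c.isupper() else 0 for c in key)
        else:
            hap = tuple(int(v) for v in key)
        if n_snps is None:
            n_snps = len(hap)
        elif len(hap) != n_snps:
            raise ValueError("haplotype keys must all have the same length")
        parsed[hap] = parsed.get(hap, 0.0) + float(freq)
    freqs = np.array(list(parsed.values()))
    if abs(freqs.sum() - 1.0) > 1e-9:
        raise ValueError(f"haplotype frequencies sum to {freqs.sum()}, not 1")
    return list(parsed.keys()), freqs


def population_r2(hap_freqs: dict, locus_a: int = 0, locus_b: int = 1) -> float:
    """Closed-form population r² between two loci of a haplotype model."""
    haps, freqs = parse_hap_freqs(hap_freqs)
    arr = np.array(haps)
    p_a = float(freqs[arr[:, locus_a] == 1].sum())
    p_b = float(freqs[arr[:, locus_b] == 1].sum())
    p_ab = float(freqs[(arr[:, locus_a] == 1) & (arr[:, locus_b] == 1)].sum())
    from .ldproxy import r2_from_hap_freqs
    return r2_from_hap_freqs(p_ab, p_a, p_b)


def gen_haplotype_block(hap_freqs: dict, n_hap: int, seed: int = 0) -> np.ndarray:
    """Sample phased haplotypes from a multinomial over specified haplotypes.

    Returns an (n_hap x n_snps) 0/1 matrix. The population r² between any
    SNP pair is computable in closed form with :func:`population_r2`.
    """
    haps, freqs = parse_hap_freqs(hap_freqs)
    rng = _rng("haplotype", seed)
    idx = rng.choice(len(haps), size=n_hap, p=freqs)
    return np.array(haps)[idx]


def gen_peak_sets(region: tuple, n_experiments: dict, planted: list,
                  seed: int = 0, n_decoys: int = 5, peak_len: int = 400) -> list:
    """Generate per-experiment peak sets with planted variant overlaps.

    Parameters
    ----------
    region : (chrom, start, end) span containing all peaks.
    n_experiments : assay class -> number of experiments, e.g.
        ``{"ATAC": 30, "H3K27ac": 6}``.
    planted : list of (pos_1based, support_counts) where support_counts
        maps assay class -> number of experiments whose peaks must cover
        the position; all other intervals avoid every planted position.

    Returns
    -------
    list of PeakExperiment; which experiments carry each planted peak is
    drawn at random (seeded), decoy intervals likewise.
    """
    chrom, start, end = region
    positions = [int(pos) for pos, _ in planted]
    for pos in positions:
        if not start < pos <= end:
            raise ValueError(f"planted position {pos} outside region")
    for _, support in planted:
        for assay, count in support.items():
            if count > n_experiments.get(assay, 0):
                raise ValueError(
                    f"support count {count} exceeds {n_experiments.get(assay, 0)} "
                    f"{assay} experiments")
    rng = _rng("peaks", seed)
    experiments = []
    for assay in sorted(n_experiments):
        total = n_experiments[assay]
        # choose which experiments cover each planted SNP
        carriers = {
            pos: set(rng.choice(total, size=int(support.get(assay, 0)), replace=False))
            for pos, support in planted
        }
        for k in range(total):
            intervals = []
            for pos in positions:
                if k in carriers[pos]:
                    offset = int(rng.integers(1, peak_len))
                    intervals.append((chrom, pos - offset, pos - offset + peak_len))
            for _ in range(n_decoys):
                for _attempt in range(100):
                    s = int(rng.integers(start, max(start + 1, end - peak_len)))
                    if all(not (s <= p - 1 < s + peak_len) for p in positions):
                        intervals.append((chrom, s, s + peak_len))
                        break
            experiments.append(PeakExperiment(
                experiment_id=f"{assay}_{k:02d}", assay=assay,
                cell_line=f"cellline_{k:02d}", intervals=intervals))
    return experiments


def gen_allelic_sequences(pwm: PWM, flank_len: int, allele_pair: tuple,
                          seed: int = 0) -> tuple:
    """Build a ref/alt sequence pair with a planted motif broken by one allele.

    The reference sequence is random flanking sequence around the PWM
    consensus, with the variant position (the motif position where the
    reference allele is most preferred by the PWM) carrying the reference
    allele. The alternate sequence differs only there.

    Returns
    -------
    (ref_seq, alt_seq, variant_offset) with the offset 0-based into the
    sequences; total length is ``2*flank_len + pwm.length``.
    """
    ref_allele, alt_allele = (a.upper() for a in allele_pair)
    if ref_allele == alt_allele:
        raise ValueError("ref and alt alleles must differ")
    bases = "ACGT"
    if ref_allele not in bases or alt_allele not in bases:
        raise ValueError("alleles must be A/C/G/T")
    rng = _rng("sequences", seed)
    motif = list(pwm.consensus)
    # place the variant where the PWM most prefers the reference allele
    col = bases.index(ref_allele)
    pos_in_motif = int(np.argmax(pwm.probs[:, col]))
    motif[pos_in_motif] = ref_allele
    flank5 = "".join(rng.choice(list(bases), size=flank_len))
    flank3 = "".join(rng.choice(list(bases), size=flank_len))
    ref_seq = flank5 + "".join(motif) + flank3
    offset = flank_len + pos_in_motif
    alt_seq = ref_seq[:offset] + alt_allele + ref_seq[offset + 1:]
    return ref_seq, alt_seq, offset


def gen_expression(genotypes, beta: float, noise_sd: float, seed: int = 0,
                   intercept: float = 10.0) -> pd.DataFrame:
    """Additive-effect genotype-expression table.

    expression = intercept + beta * dosage + Normal(0, noise_sd), clipped
    at zero to keep FPKM-like non-negativity (with the default intercept
    the clip is almost never active).
    """
    geno = np.asarray(genotypes, dtype=int)
    if not np.isin(geno, (0, 1, 2)).all():
        raise ValueError("genotypes must be coded 0/1/2")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = _rng("expression", seed)
    expr = intercept + beta * geno + rng.normal(0.0, noise_sd, size=geno.size)
    return pd.DataFrame({
        "subject_id": [f"s{i:05d}" for i in range(geno.size)],
        "genotype": geno,
        "expression": np.maximum(expr, 0.0),
    })


def gen_contacts(n_bins: int, resolution: int = 10_000, total_reads: int = 1_000_000,
                 decay_alpha: float = 1.0, loop_spec=(), seed: int = 0) -> pd.DataFrame:
    """Power-law distance-decay contact counts with planted loops.

    Expected count of a pair at distance d bins is proportional to
    ``d**-decay_alpha`` (diagonal excluded), normalised so the expected
    total equals ``total_reads``; counts are Poisson. Each loop
    (bin_i, bin_j, fold) multiplies its pair's expectation by ``fold``.

    Returns
    -------
    Triplet DataFrame (bin_i <= bin_j, count) including zero-count pairs.
    """
    if n_bins < 10:
        raise ValueError("need n_bins >= 10")
    for bi, bj, fold in loop_spec:
        if fold <= 0:
            raise ValueError("loop fold must be positive")
        if not (0 <= bi < n_bins and 0 <= bj < n_bins):
            raise ValueError("loop bins outside the matrix")
    rng = _rng("contacts", seed)
    i, j = np.triu_indices(n_bins, k=1)
    d = (j - i).astype(float)
    base = d**-decay_alpha
    mu = base * (total_reads / base.sum())
    for bi, bj, fold in loop_spec:
        lo, hi = min(bi, bj), max(bi, bj)
        mu[(i == lo) & (j == hi)] *= fold
    counts = rng.poisson(mu)
    return pd.DataFrame({"bin_i": i, "bin_j": j, "count": counts})


def gen_lipidome(class_sizes: dict | None = None, n_per_group: int = 4,
                 effect_lipids=(), target_log2fc: float = 0.0, cv: float = 0.1,
                 missing_rate: float = 0.0, seed: int = 0) -> tuple:
    """Lognormal lipid concentration matrix with planted group effects.

    Per lipid, concentrations are lognormal with coefficient of variation
    ``cv`` around a lipid-specific base level; for each effect lipid the
    treated-group mean is the control mean times ``2**target_log2fc``.
    ``effect_lipids`` may be lipid names or class names (the whole class
    is shifted). Missing entries are inserted completely at random at
    rate ``missing_rate``.

    Returns
    -------
    (matrix, class_map, groups): samples x lipids DataFrame (NaN for
    missing), lipid -> class Series, sample -> group Series with levels
    "control" < "treated".
    """
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must lie in [0, 1)")
    class_sizes = dict(DEFAULT_LIPID_CLASS_SIZES if class_sizes is None else class_sizes)
    if any(v <= 0 for v in class_sizes.values()):
        raise ValueError("class sizes must be positive")
    lipids, classes = [], []
    for cls in class_sizes:
        for k in range(class_sizes[cls]):
            lipids.append(f"{cls}_{k:03d}")
            classes.append(cls)
    class_map = pd.Series(classes, index=lipids, name="class")
    for lip in effect_lipids:
        if lip not in class_map.index and lip not in class_sizes:
            raise ValueError(f"effect lipid {lip!r} not in the class map")
    effect_cols = [l for l in lipids
                   if l in set(effect_lipids) or class_map[l] in set(effect_lipids)]

    rng = _rng("lipidome", seed)
    n_samples = 2 * n_per_group
    samples = [f"ctrl_{k}" for k in range(n_per_group)] + \
              [f"treat_{k}" for k in range(n_per_group)]
    groups = pd.Series(["control"] * n_per_group + ["treated"] * n_per_group,
                       index=samples, name="group")
    base = rng.lognormal(mean=1.0, sigma=1.0, size=len(lipids))  # uM-scale levels
    sigma = np.sqrt(np.log1p(cv**2))
    # lognormal with mean exactly `target`: mu = log(target) - sigma^2/2
    mean_mat = np.tile(base, (n_samples, 1))
    fold = 2.0**target_log2fc
    for col in effect_cols:
        mean_mat[n_per_group:, lipids.index(col)] *= fold
    draws = rng.lognormal(mean=np.log(mean_mat) - sigma**2 / 2, sigma=sigma)
    if missing_rate > 0:
        mask = rng.random(draws.shape) < missing_rate
        draws = np.where(mask, np.nan, draws)
    matrix = pd.DataFrame(draws, index=samples, columns=lipids)
    return matrix, class_map, groups


def write_bed(intervals, path) -> None:
    """Write (chrom, start, end) intervals as 0-based half-open BED."""
    with open(path, "w") as fh:
        for chrom, start, end in intervals:
            fh.write(f"{chrom}\t{start}\t{end}\n")


def write_fasta(records: dict, path) -> None:
    """Write a name -> sequence mapping as FASTA."""
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for k in range(0, len(seq), 70):
                fh.write(seq[k:k + 70] + "\n")
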