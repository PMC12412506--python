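"""Pairwise linkage disequilibrium and proxy-variant selection.

Linkage disequilibrium (LD) between two biallelic loci is summarised by
``r^2 = D^2 / (pA(1-pA) pB(1-pB))`` with ``D = pAB - pA*pB``, where ``pAB``
is the frequency of the haplotype carrying the "1" allele at both loci.
Proxies of an index GWAS SNP are the variants whose r^2 with the index
exceeds a threshold (0.8 by default); they are the candidate set for
functional follow-up because any of them could be the causal variant
tagged by the GWAS signal.

Phased haplotypes give r^2 in closed form; for unphased genotypes the
two-locus haplotype frequencies are estimated by expectation-maximisation
over the double-heterozygote phase ambiguity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LDUndefinedError",
    "EMResult",
    "LDMatrix",
    "ProxySet",
    "r2_from_haplotypes",
    "r2_from_hap_freqs",
    "r2_from_genotypes_em",
    "ld_matrix_from_haplotypes",
    "select_proxies",
]


class LDUndefinedError(ValueError):
    """LD is undefined (e.g. a monomorphic locus)."""


def r2_from_hap_freqs(p_ab: float, p_a: float, p_b: float) -> float:
    """Closed-form r² from the joint and marginal "1"-allele frequencies.

    Parameters
    ----------
    p_ab : frequency of the haplotype carrying allele 1 at both loci.
    p_a, p_b : marginal allele-1 frequencies at each locus.
    """
    if not (0 < p_a < 1 and 0 < p_b < 1):
        raise LDUndefinedError("monomorphic locus: r² undefined")
    d = p_ab - p_a * p_b
    return d * d / (p_a * (1 - p_a) * p_b * (1 - p_b))


def r2_from_haplotypes(hap_a, hap_b) -> float:
    """r² between two loci from phased binary haplotype vectors.

    Both vectors must have the same length (one entry per haplotype) and be
    polymorphic; alleles are coded 0/1.
    """
    a = np.asarray(hap_a, dtype=float)
    b = np.asarray(hap_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("haplotype vectors must be equal-length 1-D arrays")
    p_a = a.mean()
    p_b = b.mean()
    p_ab = (a * b).mean()
    return r2_from_hap_freqs(p_ab, p_a, p_b)


@dataclass
class EMResult:
    """Two-locus haplotype-frequency EM estimate from unphased genotypes."""

    r2: float
    hap_freqs: dict  # keys "11","10","01","00"
    converged: bool
    identifiable: bool
    n_iter: int

    def __float__(self) -> float:  # convenience: use result where a float is expected
        return float(self.r2)


def r2_from_genotypes_em(geno_a, geno_b, tol: float = 1e-10, max_iter: int = 1000) -> EMResult:
    """Estimate r² from unphased 0/1/2 genotype vectors via EM.

    Only double heterozygotes are phase-ambiguous: they carry either the
    coupling haplotypes (11 / 00) or the repulsion pair (10 / 01). The EM
    splits them according to the current haplotype-frequency estimates.
    On phase-unambiguous data the estimate equals the phased r² exactly.
    """
    ga = np.asarray(geno_a, dtype=int)
    gb = np.asarray(geno_b, dtype=int)
    if ga.shape != gb.shape or ga.size < 2:
        raise ValueError("need >= 2 subjects with genotypes at both loci")
    if np.any((ga < 0) | (ga > 2)) or np.any((gb < 0) | (gb > 2)):
        raise ValueError("genotypes must be coded 0/1/2")
    if len(np.unique(ga)) == 1 and ga[0] in (0, 2) or len(np.unique(gb)) == 1 and gb[0] in (0, 2):
        raise LDUndefinedError("monomorphic locus: r² undefined")

    n = ga.size
    # unambiguous haplotype counts
    n11 =np.sum((ga == 2) & (gb == 2)) * 2 + np.sum((ga == 2) & (gb == 1)) + np.sum((ga == 1) & (gb == 2))
    n10 = np.sum((ga == 2) & (gb == 0)) * 2 + np.sum((ga == 2) & (gb == 1)) + np.sum((ga == 1) & (gb == 0))
    n01 = np.sum((ga == 0) & (gb == 2)) * 2 + np.sum((ga == 0) & (gb == 1)) + np.sum((ga == 1) & (gb == 2))
    n00 = np.sum((ga == 0) & (gb == 0)) * 2 + np.sum((ga == 0) & (gb == 1)) + np.sum((ga == 1) & (gb == 0))
    n_dh = int(np.sum((ga == 1) & (gb == 1)))  # double heterozygotes

    f = np.full(4, 0.25)  # f11, f10, f01, f00
    identifiable = not (n_dh == n and n > 0)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # E-step: split double heterozygotes between coupling and repulsion
        coupling = f[0] * f[3]
        repulsion = f[1] * f[2]
        tot = coupling + repulsion
        frac = 0.5 if tot == 0 else coupling / tot
        e11 = n11 + n_dh * frac
        e10 = n10 + n_dh * (1 - frac)
        e01 = n01 + n_dh * (1 - frac)
        e00 = n00 + n_dh * frac
        new = np.array([e11, e10, e01, e00], dtype=float) / (2 * n)
        delta = np.max(np.abs(new - f))
        f = new
        if delta < tol:
            converged = True
            break
    if not converged:
        warnings.warn("haplotype EM did not converge; returning last iterate", stacklevel=2)

    p_a = f[0] + f[1]
    p_b = f[0] + f[2]
    try:
        r2 = r2_from_hap_freqs(f[0], p_a, p_b)
    except LDUndefinedError:
        r2 = float("nan")
    return EMResult(
        r2=r2,
        hap_freqs={"11": f[0], "10": f[1], "01": f[2], "00": f[3]},
        converged=converged,
        identifiable=identifiable,
        n_iter=it,
    )


@dataclass
class LDMatrix:
    """Symmetric r² matrix over an ordered set of SNPs."""

    snp_ids: list
    r2: pd.DataFrame
    positions: dict = field(default_factory=dict)  # snp_id -> bp position

    def __post_init__(self):
        vals = self.r2.to_numpy(dtype=float)
        if not np.allclose(vals, vals.T, equal_nan=True):
            raise ValueError("r² matrix must be symmetric")


@dataclass
class ProxySet:
    """Variants in LD above threshold with an index SNP."""

    index_snp: str
    threshold: float
    members: list  # of (snp_id, r2, distance_bp)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.members, columns=["snp_id", "r2", "distance_bp"])


def ld_matrix_from_haplotypes(haplotypes, snp_ids=None, positions=None) -> LDMatrix:
    """Build an LDMatrix from an (n_haplotypes x n_snps) 0/1 matrix.

    Monomorphic columns get NaN r² against everything (diagonal stays 1)
    with a warning, rather than aborting a region scan.
    """
    h = np.asarray(haplotypes, dtype=float)
    n_snp = h.shape[1]
    if snp_ids is None:
        snp_ids = [f"snp{i}" for i in range(n_snp)]
    poly = (h.var(axis=0) > 0)
    if not poly.all():
        warnings.warn(
            f"{int((~poly).sum())} monomorphic site(s): r² set to NaN", stacklevel=2
        )
    p = h.mean(axis=0)
    centered = h - p
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = centered.T @ centered / h.shape[0]
        denom = np.outer(p * (1 - p), p * (1 - p))
        r2 = np.where(denom > 0, cov**2 / denom, np.nan)
    np.fill_diagonal(r2, 1.0)
    r2[~poly, :] = np.nan
    r2[:, ~poly] = np.nan
    np.fill_diagonal(r2, 1.0)
    frame = pd.DataFrame(r2, index=snp_ids, columns=snp_ids)
    return LDMatrix(snp_ids=list(snp_ids), r2=frame, positions=dict(positions or {}))


def select_proxies(ld: LDMatrix, index_snp: str, threshold: float = 0.8,
                   inclusive: bool = False) -> ProxySet:
    """Select proxies of ``index_snp`` with r² above ``threshold``.

    The comparison is strict (> threshold) by default; ``inclusive=True``
    switches to >=. Members are sorted by genomic position when positions
    are known, else by matrix order; the index SNP is never a member.
    """
    if index_snp not in ld.r2.index:
        raise KeyError(f"index SNP {index_snp!r} not in LD matrix")
    row = ld.r2.loc[index_snp]
    members = []
    for snp_id, r2 in row.items():
        if snp_id == index_snp or not np.isfinite(r2):
            continue
        if (r2 >= threshold) if inclusive else (r2 > threshold):
            dist = abs(ld.positions.get(snp_id, 0) - ld.positions.get(index_snp, 0)) \
                if ld.positions else 0
            members.append((snp_id, float(r2), int(dist)))
    if ld.positions:
        members.sort(key=lambda m: ld.positions.get(m[0], 0))
    return ProxySet(index_snp=index_snp, threshold=threshold, members=members)
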