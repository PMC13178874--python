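"""Toy-scale genotype simulation and latent-phenotype association scanning.

SNPs are simulated independently (no linkage disequilibrium) with uniform
minor-allele frequencies and map positions spaced far enough apart that every
SNP is its own locus by construction; correlated SNPs only enter through
explicit duplication in tests, which is what exercises the clumping rule.

The association scan is a closed-form ordinary least squares of each latent
on each SNP (optionally covariate-adjusted), a desk-scale stand-in for a
mixed-model GWAS. Multi-trait significance uses the Bonferroni-adjusted
minimum p-value across latents — a valid family-wise error rate control that
replaces heavier multi-trait combination machinery. Significant SNPs are
reduced to independent loci by greedy clumping with an r-squared and distance
window rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GenotypeMatrix",
    "simulate_genotypes",
    "AssociationResult",
    "association_scan",
    "min_p_combine",
    "count_significant_loci",
    "recovery_comparison",
]


@dataclass
class GenotypeMatrix:
    """Subjects x SNPs additive genotypes in {0, 1, 2} plus a toy map."""

    genotypes: np.ndarray  # (n_subjects, n_snps) int8
    maf: np.ndarray  # per-SNP target minor-allele frequency
    snp_map: pd.DataFrame  # columns: snp, chrom, bp, maf
    subjects: list[str] | None = None

    @property
    def n_subjects(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    def empirical_maf(self) -> np.ndarray:
        freq = self.genotypes.mean(axis=0) / 2.0
        return np.minimum(freq, 1.0 - freq)

    def monomorphic(self) -> np.ndarray:
        return self.genotypes.std(axis=0) == 0

    def write(self, prefix) -> None:
        """Write as a transposed text matrix (SNPs x subjects) plus a map file."""
        prefix = Path(prefix)
        np.savetxt(prefix.with_suffix(".geno.txt"), self.genotypes.T, fmt="%d")
        self.snp_map.to_csv(prefix.with_suffix(".map.txt"), sep="\t", index=False)

    @classmethod
    def read(cls, prefix) -> "GenotypeMatrix":
        prefix = Path(prefix)
        g = np.loadtxt(prefix.with_suffix(".geno.txt"), dtype=np.int8, ndmin=2).T
        snp_map = pd.read_csv(prefix.with_suffix(".map.txt"), sep="\t")
        return cls(genotypes=g, maf=snp_map["maf"].to_numpy(), snp_map=snp_map)


#: spacing guaranteeing all simulated SNPs are clump-independent at 250 kb
_SNP_SPACING_BP = 600_000


def simulate_genotypes(
    n_subjects: int,
    n_snps: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
) -> GenotypeMatrix:
    """Independent SNPs with g ~ Binomial(2, maf), maf ~ U(maf_range)."""
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError(f"maf_range must lie within (0, 0.5], got {maf_range}")
    rng = np.random.default_rng(seed)
    maf = rng.uniform(lo, hi, size=n_snps)
    g = rng.binomial(2, maf[None, :], size=(n_subjects, n_snps)).astype(np.int8)
    snp_map = pd.DataFrame(
        {
            "snp": [f"snp{i:04d}" for i in range(n_snps)],
            "chrom": 1,
            "bp": 1_000_000 + _SNP_SPACING_BP * np.arange(n_snps),
            "maf": maf,
        }
    )
    return GenotypeMatrix(genotypes=g, maf=maf, snp_map=snp_map)


@dataclass
class AssociationResult:
    """Per-(SNP, latent) OLS statistics plus per-SNP min-P machinery."""

    effect: pd.DataFrame  # SNPs x latents
    se: pd.DataFrame
    pvalues: pd.DataFrame
    n: int
    dof: int
    excluded: list[str]  # rank-deficient SNPs
    snp_map: pd.DataFrame

    def min_p(self) -> pd.Series:
        return self.pvalues.min(axis=1)

    def best_latent(self) -> pd.Series:
        return self.pvalues.idxmin(axis=1)

    def summary(self, top: int = 10) -> pd.DataFrame:
        adj = min_p_combine(self)
        out = pd.DataFrame(
            {
                "min_p": self.min_p(),
                "adjusted_p": adj,
                "best_latent": self.best_latent(),
            }
        )
        return out.sort_values("adjusted_p").head(top)


def association_scan(
    latents: pd.DataFrame,
    genotypes: GenotypeMatrix,
    covariates: pd.DataFrame | None = None,
) -> AssociationResult:
    """Closed-form OLS of every latent on every SNP with two-sided t-tests."""
    Y = np.asarray(latents, dtype=np.float64)
    G = genotypes.genotypes.astype(np.float64)
    if len(Y) != len(G):
        raise ValueError(f"{len(Y)} latent rows vs {len(G)} genotype rows")
    n = len(Y)
    n_cov = 0
    if covariates is not None:
        C = np.column_stack([np.ones(n), np.asarray(covariates, dtype=np.float64)])
        n_cov = C.shape[1] - 1
        # Frisch-Waugh: residualize both sides on the covariates
        Q, _ = np.linalg.qr(C)
        Y = Y - Q @ (Q.T @ Y)
        G = G - Q @ (Q.T @ G)
    else:
        Y = Y - Y.mean(axis=0)
        G = G - G.mean(axis=0)
    dof = n - 2 - n_cov
    if dof < 1:
        raise ValueError("not enough samples for the requested model")

    gg = (G**2).sum(axis=0)
    ok = gg > 0
    num = G.T @ Y  # (m, L)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = num / gg[:, None]
        rss = (Y**2).sum(axis=0)[None, :] - beta**2 * gg[:, None]
        sigma2 = np.maximum(rss, 0.0) / dof
        se = np.sqrt(sigma2 / gg[:, None])
        tstat = beta / se
    pvals = 2.0 * sps.t.sf(np.abs(tstat), dof)
    pvals = np.maximum(pvals, np.finfo(float).tiny)  # p in (0, 1]
    beta[~ok], se[~ok], pvals[~ok] = np.nan, np.nan, np.nan

    snps = list(genotypes.snp_map["snp"])
    cols = list(latents.columns) if isinstance(latents, pd.DataFrame) else list(range(Y.shape[1]))
    excluded = [snps[i] for i in np.flatnonzero(~ok)]
    return AssociationResult(
        effect=pd.DataFrame(beta, index=snps, columns=cols),
        se=pd.DataFrame(se, index=snps, columns=cols),
        pvalues=pd.DataFrame(pvals, index=snps, columns=cols),
        n=n,
        dof=dof,
        excluded=excluded,
        snp_map=genotypes.snp_map,
    )


def min_p_combine(result: AssociationResult | pd.DataFrame, n_latents: int | None = None) -> pd.Series:
    """Bonferroni-adjusted minimum p across latents: min(1, L * min_j p_j)."""
    p = result.pvalues if isinstance(result, AssociationResult) else result
    L = n_latents if n_latents is not None else p.shape[1]
    return np.minimum(1.0, L * p.min(axis=1))


@dataclass
class LocusAssignment:
    n_loci: int
    assignments: pd.DataFrame  # significant SNPs: snp, locus, adjusted_p, is_index


def count_significant_loci(
    result: AssociationResult,
    genotypes: GenotypeMatrix,
    threshold: float = 5e-8,
    clump_r2: float = 0.1,
    window_kb: float = 250.0,
) -> LocusAssignment:
    """Greedy clumping of significant SNPs into independent loci.

    Repeatedly take the most significant remaining SNP with adjusted p below
    ``threshold`` as a locus index SNP, then absorb every SNP within
    ``window_kb`` whose genotype correlation squared exceeds ``clump_r2``.
    """
    adj = min_p_combine(result)
    sig = adj[adj < threshold].dropna().sort_values()
    if sig.empty:
        return LocusAssignment(n_loci=0, assignments=pd.DataFrame(columns=["snp", "locus", "adjusted_p", "is_index"]))

    snp_pos = result.snp_map.set_index("snp")["bp"]
    snp_idx = {s: i for i, s in enumerate(result.snp_map["snp"])}
    G = genotypes.genotypes.astype(np.float64)
    Gc = G - G.mean(axis=0)
    norms = np.sqrt((Gc**2).sum(axis=0))

    remaining = list(sig.index)
    rows = []
    locus = 0
    while remaining:
        index_snp = remaining[0]
        rows.append({"snp": index_snp, "locus": locus, "adjusted_p": float(adj[index_snp]), "is_index": True})
        i = snp_idx[index_snp]
        clumped = []
        for other in remaining[1:]:
            j = snp_idx[other]
            if abs(snp_pos[other] - snp_pos[index_snp]) <= window_kb * 1000:
                denom = norms[i] * norms[j]
                r2 = float((Gc[:, i] @ Gc[:, j]) / denom) ** 2 if denom > 0 else 0.0
                if r2 > clump_r2:
                    clumped.append(other)
                    rows.append(
                        {"snp": other, "locus": locus, "adjusted_p": float(adj[other]), "is_index": False}
                    )
        remaining = [s for s in remaining[1:] if s not in clumped]
        locus += 1
    return LocusAssignment(n_loci=locus, assignments=pd.DataFrame(rows))


def recovery_comparison(
    savae_result: AssociationResult,
    monolithic_result: AssociationResult,
    causal_map: Sequence[tuple[int, str, str]],
    threshold: float,
    stream_of_factor: Mapping[str, str] | None = None,
) -> dict:
    """Causal-SNP recovery rates and stream attribution accuracy.

    ``causal_map`` lists (snp index, factor name, target stream). A causal SNP
    counts as recovered when its Bonferroni-adjusted min-P clears the
    threshold; attribution is correct when the recovered SNP's best-associated
    latent carries the prefix of the causally targeted stream.
    """
    if stream_of_factor is None:
        from .simulate import STREAM_FACTORS

        stream_of_factor = {f: s for s, fs in STREAM_FACTORS.items() for f in fs}

    out: dict = {"n_causal": len(causal_map)}
    for tag, res in (("savae", savae_result), ("monolithic", monolithic_result)):
        adj = min_p_combine(res)
        snps = list(res.pvalues.index)
        recovered = []
        correct = 0
        for snp_i, factor, stream in causal_map:
            name = snps[snp_i]
            if float(adj[name]) < threshold:
                recovered.append(name)
                target = stream or stream_of_factor.get(factor, "")
                best = str(res.best_latent()[name])
                if tag == "savae" and best.rsplit("_z", 1)[0] == target:
                    correct += 1
        out[f"{tag}_recovered"] = len(recovered)
        out[f"{tag}_recovery_rate"] = len(recovered) / max(len(causal_map), 1)
        if tag == "savae":
            out["attribution_correct"] = correct
            out["attribution_accuracy"] = correct / max(len(recovered), 1)
    return out
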