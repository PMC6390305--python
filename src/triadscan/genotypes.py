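"""Genotype data model, VCF/tabular I/O, depth-based calling, and filtering.

Genotypes are stored as minor-allele dosage (0, 1, 2) per individual x locus,
with -1 marking missing calls. The minor allele is defined globally across all
individuals in the dataset; per-population frequencies derive from this fixed
polarization. Positions are 1-based (VCF convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binom

logger = logging.getLogger(__name__)

MISSING = -1

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "DepthMatrix",
    "FilterReport",
    "read_genotypes",
    "read_popmap",
    "write_vcf",
    "write_tabular",
    "call_genotypes",
    "filter_dataset",
    "hwe_exact_test",
]


@dataclass
class GenotypeMatrix:
    """Individuals x biallelic loci with 0/1/2/missing minor-allele dosage.

    Attributes
    ----------
    genotypes : (n_individuals, n_loci) int8 array, values in {0, 1, 2, -1}.
    loci : DataFrame with columns scaffold, pos (1-based), ref, alt and a
        boolean column ``minor_is_alt`` recording the global polarization.
    individuals : DataFrame with columns id, population.
    populations : ordered list of population labels.
    """

    genotypes: np.ndarray
    loci: pd.DataFrame
    individuals: pd.DataFrame
    populations: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise ValueError("genotypes must be 2-D (individuals x loci)")
        n_ind, n_loc = self.genotypes.shape
        if len(self.individuals) != n_ind or len(self.loci) != n_loc:
            raise ValueError("metadata dimensions do not match genotype matrix")
        bad = ~np.isin(self.genotypes, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError("dosage values must be in {0, 1, 2, missing}")
        if not self.populations:
            self.populations = list(pd.unique(self.individuals["population"]))
        unknown = set(self.individuals["population"]) - set(self.populations)
        if unknown:
            raise ValueError(f"individuals reference unknown populations: {unknown}")
        for scaf, sub in self.loci.groupby("scaffold", sort=False):
            p = sub["pos"].to_numpy()
            if not np.all(np.diff(p) > 0):
                raise ValueError(f"positions not strictly increasing on {scaf}")

    @property
    def n_individuals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]

    def pop_indices(self, population: str) -> np.ndarray:
        if population not in self.populations:
            raise KeyError(f"population {population!r} not in dataset")
        return np.flatnonzero((self.individuals["population"] == population).to_numpy())

    def subset(self, ind_mask=None, locus_mask=None) -> "GenotypeMatrix":
        g = self.genotypes
        ind = self.individuals
        loc = self.loci
        if ind_mask is not None:
            g = g[ind_mask]
            ind = ind.iloc[np.flatnonzero(ind_mask) if np.asarray(ind_mask).dtype == bool else ind_mask]
        if locus_mask is not None:
            g = g[:, locus_mask]
            loc = loc.iloc[np.flatnonzero(locus_mask) if np.asarray(locus_mask).dtype == bool else locus_mask]
        pops = [p for p in self.populations if p in set(ind["population"])]
        return GenotypeMatrix(g.copy(), loc.reset_index(drop=True), ind.reset_index(drop=True), pops)

    def allele_freq(self, population: str | None = None) -> np.ndarray:
        """Minor-allele frequency per locus over called genotypes (NaN if none)."""
        if population is None:
            g = self.genotypes
        else:
            g = self.genotypes[self.pop_indices(population)]
        called = g != MISSING
        n = 2.0 * called.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(called, g, 0).sum(axis=0) / n

    def missingness_per_individual(self) -> np.ndarray:
        return (self.genotypes == MISSING).mean(axis=1)

    def call_rate_per_locus(self) -> np.ndarray:
        return (self.genotypes != MISSING).mean(axis=0)


@dataclass
class DepthMatrix:
    """Per individual x locus read counts for the two alleles of a GBS tag.

    counts[..., 0] is the reference-allele depth, counts[..., 1] the alternate.
    Each is capped (default 127 reads per allele, the cap used by tag-based
    GBS genotypers), so the total per cell is at most 2*cap.
    """

    counts: np.ndarray  # (n_ind, n_loci, 2)
    cap: int = 127

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 3 or self.counts.shape[2] != 2:
            raise ValueError("counts must have shape (n_ind, n_loci, 2)")
        if (self.counts < 0).any():
            raise ValueError("negative read counts")
        if (self.counts > self.cap).any():
            raise ValueError(f"per-allele count exceeds cap {self.cap}")

    @property
    def total(self) -> np.ndarray:
        return self.counts.sum(axis=2)


@dataclass
class FilterReport:
    """Record of the filtering cascade: what each rule removed, in order."""

    rules: list[str]
    individuals_removed: dict[str, int]
    loci_removed: dict[str, int]
    input_shape: tuple[int, int]
    output_shape: tuple[int, int]

    def __post_init__(self):
        ni, nl = self.input_shape
        if ni - sum(self.individuals_removed.values()) != self.output_shape[0]:
            raise ValueError("individual removals inconsistent with shapes")
        if nl - sum(self.loci_removed.values()) != self.output_shape[1]:
            raise ValueError("locus removals inconsistent with shapes")

    def to_dict(self) -> dict:
        return {
            "rules": self.rules,
            "individuals_removed": self.individuals_removed,
            "loci_removed": self.loci_removed,
            "input_shape": list(self.input_shape),
            "output_shape": list(self.output_shape),
        }


def read_popmap(path) -> pd.DataFrame:
    """Read a two-column TSV (individual id, population label)."""
    pm = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if pm.shape[1] < 2:
        raise ValueError("popmap must have two columns: individual, population")
    pm = pm.iloc[:, :2]
    pm.columns = ["id", "population"]
    return pm


def _polarize_minor(genotypes: np.ndarray, loci: pd.DataFrame) -> tuple[np.ndarray, pd.DataFrame]:
    """Flip dosages so they count the globally minor allele.

    On input dosage counts the alt allele. Ties (freq exactly 0.5) keep alt.
    """
    called = genotypes != MISSING
    n = 2.0 * called.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        alt_freq = np.where(called, genotypes, 0).sum(axis=0) / n
    minor_is_alt = ~(alt_freq > 0.5)
    flip = ~minor_is_alt
    out = genotypes.copy()
    cols = np.flatnonzero(flip)
    sub = out[:, cols]
    sub[sub != MISSING] = 2 - sub[sub != MISSING]
    out[:, cols] = sub
    loci = loci.copy()
    loci["minor_is_alt"] = minor_is_alt
    return out, loci


def _read_vcf(path, sample_to_pop: dict[str, str]) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    unknown = [s for s in samples if s not in sample_to_pop]
    if unknown:
        raise ValueError(f"sample ids absent from popmap: {unknown}")
    rows, recs = [], []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_multi += 1
            continue
        gt = np.asarray(var.gt_types, dtype=np.int8)  # 0,1,2 alt dosage; 3=missing
        gt[gt == 3] = MISSING
        rows.append(gt)
        recs.append((var.CHROM, var.POS, var.REF, var.ALT[0]))
    if n_multi:
        logger.info("dropped %d non-biallelic-SNP records", n_multi)
    if not rows:
        raise ValueError("no loci: VCF contained no biallelic SNP records")
    genotypes = np.vstack(rows).T  # individuals x loci
    loci = pd.DataFrame(recs, columns=["scaffold", "pos", "ref", "alt"])
    individuals = pd.DataFrame(
        {"id": samples, "population": [sample_to_pop[s] for s in samples]}
    )
    genotypes, loci = _polarize_minor(genotypes, loci)
    return GenotypeMatrix(genotypes, loci, individuals)


def _read_tabular(path, sample_to_pop: dict[str, str]) -> GenotypeMatrix:
    tab = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if tab.shape[1] == 0:
        raise ValueError("no loci: tabular genotype file has no locus columns")
    unknown = [s for s in tab.index if s not in sample_to_pop]
    if unknown:
        raise ValueError(f"sample ids absent from popmap: {unknown}")
    recs = []
    for col in tab.columns:
        try:
            scaf, pos = col.rsplit(":", 1)
            recs.append((scaf, int(pos), "A", "C"))
        except ValueError as exc:
            raise ValueError(f"malformed locus id {col!r} (want scaffold:pos)") from exc
    geno = tab.replace({"NA": str(MISSING), ".": str(MISSING), "": str(MISSING)})
    genotypes = geno.to_numpy(dtype=float).astype(np.int8)
    loci = pd.DataFrame(recs, columns=["scaffold", "pos", "ref", "alt"])
    individuals = pd.DataFrame(
        {"id": list(tab.index), "population": [sample_to_pop[s] for s in tab.index]}
    )
    genotypes, loci = _polarize_minor(genotypes, loci)
    return GenotypeMatrix(genotypes, loci, individuals)


def read_genotypes(path, popmap) -> GenotypeMatrix:
    """Read genotypes from VCF (.vcf/.vcf.gz) or the tabular TSV format.

    ``popmap`` is a path to an individual->population TSV or a DataFrame with
    columns (id, population). Non-biallelic records are dropped with a logged
    count; dosages are polarized on the globally minor allele.
    """
    if not isinstance(popmap, pd.DataFrame):
        popmap = read_popmap(popmap)
    sample_to_pop = dict(zip(popmap["id"], popmap["population"]))
    p = str(path)
    if p.endswith((".vcf", ".vcf.gz", ".bcf")):
        return _read_vcf(p, sample_to_pop)
    return _read_tabular(p, sample_to_pop)


def write_vcf(g: GenotypeMatrix, path, depths: DepthMatrix | None = None) -> None:
    """Write a minimal VCF 4.2 with GT (and AD when depths are given)."""
    geno = g.genotypes
    minor_is_alt = g.loci.get("minor_is_alt", pd.Series(True, index=g.loci.index)).to_numpy()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if depths is not None:
            fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allele depths">\n')
        for scaf in pd.unique(g.loci["scaffold"]):
            fh.write(f"##contig=<ID={scaf}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(g.individuals["id"]) + "\n")
        gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        for j in range(g.n_loci):
            row = g.loci.iloc[j]
            # convert minor-allele dosage back to alt-allele dosage
            dos = geno[:, j].copy()
            if not minor_is_alt[j]:
                dos[dos != MISSING] = 2 - dos[dos != MISSING]
            fields = [
                str(row["scaffold"]), str(int(row["pos"])), ".",
                str(row["ref"]), str(row["alt"]), ".", "PASS", ".",
                "GT" if depths is None else "GT:AD",
            ]
            cells = []
            for i in range(g.n_individuals):
                s = gt_strings[int(dos[i])]
                if depths is not None:
                    ad = depths.counts[i, j]
                    s += f":{int(ad[0])},{int(ad[1])}"
                cells.append(s)
            fh.write("\t".join(fields + cells) + "\n")


def write_tabular(g: GenotypeMatrix, path) -> None:
    """Write the tabular TSV genotype format (rows=individuals, cols=scaffold:pos)."""
    cols = [f"{r.scaffold}:{int(r.pos)}" for r in g.loci.itertuples()]
    df = pd.DataFrame(g.genotypes, index=g.individuals["id"], columns=cols)
    df.to_csv(path, sep="\t")


def call_genotypes(
    depths: DepthMatrix,
    error_rate: float = 0.01,
    min_reads: int = 5,
    loci: pd.DataFrame | None = None,
    individuals: pd.DataFrame | None = None,
) -> GenotypeMatrix:
    """Call genotypes from allele depths by maximum binomial likelihood.

    Per cell with counts (a, b) = (ref reads, alt reads) and n = a + b, the
    three genotype likelihoods are Binomial(n, eps), Binomial(n, 0.5) and
    Binomial(n, 1 - eps) for the alt count b; the maximizing genotype is
    called. Cells with n < ``min_reads`` are set to missing.
    """
    if not 0.0 < error_rate < 0.5:
        raise ValueError("error_rate must be in (0, 0.5)")
    a = depths.counts[..., 0].astype(np.int64)
    b = depths.counts[..., 1].astype(np.int64)
    n = a + b
    with np.errstate(divide="ignore"):
        ll_hom_ref = binom.logpmf(b, n, error_rate)
        ll_het = binom.logpmf(b, n, 0.5)
        ll_hom_alt = binom.logpmf(b, n, 1.0 - error_rate)
    stacked = np.stack([ll_hom_ref, ll_het, ll_hom_alt])
    calls = np.argmax(stacked, axis=0).astype(np.int8)  # alt dosage
    calls[n < min_reads] = MISSING
    n_ind, n_loc = calls.shape
    if loci is None:
        loci = pd.DataFrame(
            {"scaffold": ["scaf0"] * n_loc, "pos": np.arange(1, n_loc + 1),
             "ref": "A", "alt": "C"}
        )
    if individuals is None:
        individuals = pd.DataFrame(
            {"id": [f"ind{i}" for i in range(n_ind)], "population": "pop0"}
        )
    calls, loci = _polarize_minor(calls, loci)
    return GenotypeMatrix(calls, loci, individuals)


from functools import lru_cache


@lru_cache(maxsize=200_000)
def hwe_exact_test(nAA: int, nAa: int, naa: int) -> tuple[float, int]:
    """Exact conditional Hardy-Weinberg test for one biallelic locus.

    Enumerates the conditional distribution of the heterozygote count given
    the observed allele counts and returns the two-sided p-value (sum of
    probabilities of outcomes no more probable than the observed one) and the
    sign of H_o - H_e (+1 excess heterozygosity, -1 deficit, 0 neither).
    Monomorphic loci return (1.0, 0).
    """
    if min(nAA, nAa, naa) < 0 or nAA + nAa + naa == 0:
        raise ValueError("counts must be non-negative with positive total")
    n = nAA + nAa + naa
    nA = 2 * nAA + nAa
    na = 2 * n - nA
    if nA == 0 or na == 0:
        return 1.0, 0
    rare = min(nA, na)
    # possible heterozygote counts share parity with the rare allele count
    hets = np.arange(rare % 2, rare + 1, 2)
    # log conditional probabilities (Levene / Haldane distribution)
    from scipy.special import gammaln

    def logp(h):
        hom_r = (rare - h) // 2
        hom_c = (2 * n - rare - h) // 2
        return (
            h * np.log(2.0)
            + gammaln(n + 1) - gammaln(hom_r + 1) - gammaln(h + 1) - gammaln(hom_c + 1)
            - (gammaln(2 * n + 1) - gammaln(rare + 1) - gammaln(2 * n - rare + 1))
        )

    lp = logp(hets)
    probs = np.exp(lp - lp.max())
    probs /= probs.sum()
    obs = probs[hets == nAa][0]
    p = float(probs[probs <= obs * (1 + 1e-12)].sum())
    p_freq = nA / (2.0 * n)
    h_exp = 2.0 * p_freq * (1.0 - p_freq)
    h_obs = nAa / n
    direction = 0 if np.isclose(h_obs, h_exp) else (1 if h_obs > h_exp else -1)
    return min(p, 1.0), direction


def filter_dataset(
    g: GenotypeMatrix,
    max_ind_missing: float = 0.125,
    min_locus_callrate: float = 0.85,
    min_maf: float = 0.01,
    hwe_alpha: float = 0.01,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the SNP/individual filtering cascade, in order.

    1. drop individuals with missingness > ``max_ind_missing``;
    2. drop loci called in fewer than ``min_locus_callrate`` of the rest;
    3. drop loci with global MAF < ``min_maf`` (recomputed after 1-2; ties at
       the threshold are retained);
    4. drop loci with observed > expected heterozygosity whose exact HWE
       p-value is below ``hwe_alpha`` (excess-heterozygosity direction only).
    """
    for thr in (max_ind_missing, min_locus_callrate, min_maf, hwe_alpha):
        if not 0.0 <= thr <= 1.0:
            raise ValueError("thresholds must lie in [0, 1]")
    input_shape = (g.n_individuals, g.n_loci)
    ind_removed, loci_removed = {}, {}

    keep_ind = g.missingness_per_individual() <= max_ind_missing
    ind_removed["individual_missingness"] = int((~keep_ind).sum())
    g = g.subset(ind_mask=keep_ind)
    if g.n_individuals == 0:
        raise ValueError("empty result after stage individual_missingness")

    keep_loc = g.call_rate_per_locus() >= min_locus_callrate
    loci_removed["locus_callrate"] = int((~keep_loc).sum())
    g = g.subset(locus_mask=keep_loc)
    if g.n_loci == 0:
        raise ValueError("empty result after stage locus_callrate")

    freq = g.allele_freq()
    maf = np.minimum(freq, 1.0 - freq)
    keep_loc = ~(maf < min_maf)
    loci_removed["minor_allele_frequency"] = int((~keep_loc).sum())
    g = g.subset(locus_mask=keep_loc)
    if g.n_loci == 0:
        raise ValueError("empty result after stage minor_allele_frequency")

    geno = g.genotypes
    keep = np.ones(g.n_loci, dtype=bool)
    for j in range(g.n_loci):
        col = geno[:, j]
        col = col[col != MISSING]
        n_het = int((col == 1).sum())
        n_hom_min = int((col == 2).sum())
        n_hom_maj = int((col == 0).sum())
        p, direction = hwe_exact_test(n_hom_maj, n_het, n_hom_min)
        if direction > 0 and p < hwe_alpha:
            keep[j] = False
    loci_removed["hwe_excess_heterozygosity"] = int((~keep).sum())
    g = g.subset(locus_mask=keep)
    if g.n_loci == 0:
        raise ValueError("empty result after stage hwe_excess_heterozygosity")

    # re-polarize: the minor allele may change after removing individuals
    geno, loci = _polarize_minor(g.genotypes, g.loci.drop(columns=["minor_is_alt"], errors="ignore"))
    if "minor_is_alt" in g.loci:
        loci["minor_is_alt"] = np.asarray(g.loci["minor_is_alt"]) == np.asarray(loci["minor_is_alt"])
    g = GenotypeMatrix(geno, loci, g.individuals, g.populations)

    report = FilterReport(
        rules=[
            "individual_missingness",
            "locus_callrate",
            "minor_allele_frequency",
            "hwe_excess_heterozygosity",
        ],
        individuals_removed={**ind_removed,
                             "locus_callrate": 0,
                             "minor_allele_frequency": 0,
                             "hwe_excess_heterozygosity": 0},
        loci_removed={"individual_missingness": 0, **loci_removed},
        input_shape=input_shape,
        output_shape=(g.n_individuals, g.n_loci),
    )
    return g, report
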