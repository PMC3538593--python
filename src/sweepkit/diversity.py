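"""Within-species diversity and between-species divergence statistics.

Implements the region/gene summary statistics: segregating sites S (with
singleton counts), nucleotide diversity pi per functional class, Watterson's
theta_W and the high-frequency-weighted theta_L, haplotype number and
diversity, Jukes-Cantor-corrected divergence K per class, and NG86 Ka/Ks
with equal weighting of all shortest mutational pathways between codons.

All per-class estimates use fractional effective site counts from
`sweepkit.regions.classify_sites` as denominators, so synonymous and
nonsynonymous quantities are on the usual NG86 per-site scale.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from sweepkit._util import UNDEFINED, UndefinedStatistic, harmonic
from sweepkit.regions import (
    HaplotypeAlignment,
    PolymorphismTable,
    SiteClass,
    SiteClassification,
    _codon_table,
    _oriented_base,
    codon_syn_fractions,
    variant_table,
)


class SaturationError(ValueError):
    """Observed divergence exceeds the Jukes-Cantor domain (p >= 3/4)."""


@dataclass
class SiteFrequencySpectrum:
    """Unfolded SFS: xi[i-1] = number of sites with derived count i."""

    n: int
    xi: np.ndarray

    def __post_init__(self):
        self.xi = np.asarray(self.xi, dtype=float)
        if len(self.xi) != self.n - 1:
            raise ValueError(f"xi must have length n-1={self.n - 1}")
        if (self.xi < 0).any():
            raise ValueError("xi counts must be non-negative")

    @property
    def S(self) -> int:
        return int(round(self.xi.sum()))

    @classmethod
    def from_counts(cls, n: int, derived_counts) -> "SiteFrequencySpectrum":
        xi = np.bincount(np.asarray(derived_counts, dtype=int), minlength=n)[1:n]
        return cls(n=n, xi=xi)

    @classmethod
    def from_table(cls, table: PolymorphismTable) -> "SiteFrequencySpectrum":
        pol = table.polarized()
        return cls.from_counts(table.n, pol["derived_count"].to_numpy(dtype=int))

    def theta_pi_count(self) -> float:
        """Pairwise-diversity estimator in per-locus (count) units."""
        i = np.arange(1, self.n)
        return float(np.sum(self.xi * 2.0 * i * (self.n - i)) / (self.n * (self.n - 1)))

    def theta_L_count(self) -> float:
        """Zeng et al. theta_L in per-locus (count) units."""
        i = np.arange(1, self.n)
        return float(np.sum(i * self.xi) / (self.n - 1))


def _class_row_mask(df: pd.DataFrame, class_filter: Optional[str]) -> pd.Series:
    if class_filter in (None, "total"):
        return pd.Series(True, index=df.index)
    if class_filter == "silent":
        return df["class"].isin(["intronic", "intergenic"]) | (
            df["change_type"] == "synonymous"
        )
    if class_filter in ("synonymous", "nonsynonymous"):
        return df["change_type"] == class_filter
    if class_filter == "noncoding":
        return df["class"].isin(["intronic", "intergenic"])
    if class_filter in ("intronic", "intergenic", "coding"):
        return df["class"] == class_filter
    raise ValueError(f"unknown class filter {class_filter!r}")


def segregating_sites(
    table: PolymorphismTable, class_filter: Optional[str] = None
) -> tuple[int, int]:
    """(S, singletons) for the requested functional class.

    A coding segregating site counts as synonymous or nonsynonymous according
    to the majority classification of its observed change; multiallelic sites
    count once.
    """
    if not len(table.df):
        return 0, 0
    sub = table.df[_class_row_mask(table.df, class_filter)]
    return int(len(sub)), int(sub["singleton"].sum())


def _pair_diffs_from_alleles(allele_str: str) -> int:
    counts = np.array([int(x.split(":")[1]) for x in allele_str.split(",")])
    n = counts.sum()
    return int(n * (n - 1) // 2 - np.sum(counts * (counts - 1) // 2))


def _column_weights(df: pd.DataFrame, class_filter: Optional[str]) -> np.ndarray:
    """Per-segregating-site contribution weight to the class numerator."""
    w = np.zeros(len(df))
    coding = (df["class"] == "coding").to_numpy()
    noncoding = df["class"].isin(["intronic", "intergenic"]).to_numpy()
    syn_w = df["change_syn_weight"].to_numpy(dtype=float)
    if class_filter in (None, "total"):
        w[coding | noncoding] = 1.0
    elif class_filter == "coding":
        w[coding] = 1.0
    elif class_filter == "noncoding":
        w[noncoding] = 1.0
    elif class_filter in ("intronic", "intergenic"):
        w[(df["class"] == class_filter).to_numpy()] = 1.0
    elif class_filter == "synonymous":
        w[coding] = syn_w[coding]
    elif class_filter == "nonsynonymous":
        w[coding] = 1.0 - syn_w[coding]
    elif class_filter == "silent":
        w[noncoding] = 1.0
        w[coding] = syn_w[coding]
    else:
        raise ValueError(f"unknown class filter {class_filter!r}")
    return w


def nucleotide_diversity(
    aln: HaplotypeAlignment,
    classification: Optional[SiteClassification] = None,
    class_filter: Optional[str] = None,
    table: Optional[PolymorphismTable] = None,
):
    """Per-site nucleotide diversity pi for the requested class.

    pi = sum over included columns of pairwise differences, divided by
    C(n,2) x effective sites in the class. Coding columns contribute with the
    synonymous weight of their observed change under synonymous/silent
    filters. Returns an UndefinedStatistic when the class has zero sites.
    """
    if table is None:
        table = variant_table(aln, classification)
    n = table.n
    if classification is not None:
        sites = classification.counts[
            "total" if class_filter is None else class_filter
        ]
    else:
        mat = aln.matrix
        sites = float(np.sum(~(np.isin(mat, ["N", "-"]).any(axis=0))))
        if class_filter not in (None, "total"):
            raise ValueError("class filters require a SiteClassification")
    if sites <= 0:
        return UNDEFINED
    if not len(table.df):
        return 0.0
    diffs = np.array([_pair_diffs_from_alleles(a) for a in table.df["alleles"]])
    if classification is not None:
        w = _column_weights(table.df, class_filter)
    else:
        w = np.ones(len(table.df))
    npairs = n * (n - 1) / 2.0
    return float(np.sum(diffs * w) / (npairs * sites))


def mean_pairwise_differences(
    table: PolymorphismTable, class_filter: Optional[str] = None
) -> float:
    """Mean pairwise difference count (per locus, not per site)."""
    if not len(table.df):
        return 0.0
    sub = table.df[_class_row_mask(table.df, class_filter)]
    if not len(sub):
        return 0.0
    diffs = np.array([_pair_diffs_from_alleles(a) for a in sub["alleles"]])
    npairs = table.n * (table.n - 1) / 2.0
    return float(diffs.sum() / npairs)


def theta_estimators(
    sfs: SiteFrequencySpectrum, effective_sites: float
) -> tuple[float, float]:
    """(theta_W, theta_L) per site from the unfolded SFS.

    theta_W = S / (a_n x sites); theta_L = sum i*xi_i / ((n-1) x sites).
    """
    if effective_sites <= 0:
        raise ValueError("effective_sites must be positive")
    if sfs.S == 0:
        return 0.0, 0.0
    theta_w = sfs.S / (harmonic(sfs.n) * effective_sites)
    theta_l = sfs.theta_L_count() / effective_sites
    return float(theta_w), float(theta_l)


def watterson_theta(S: int, n: int, effective_sites: float) -> float:
    """theta_W from a segregating-site count alone (folded data suffice)."""
    if effective_sites <= 0:
        raise ValueError("effective_sites must be positive")
    return float(S / (harmonic(n) * effective_sites))


def haplotype_statistics(
    aln: HaplotypeAlignment,
    classification: Optional[SiteClassification] = None,
    class_filter: Optional[str] = None,
) -> tuple[int, float]:
    """(h, Hd): distinct haplotypes and Nei haplotype diversity.

    Haplotypes are compared over the included columns of the requested class;
    Hd = n/(n-1) x (1 - sum p_i^2).
    """
    mat = aln.matrix
    n = aln.n
    if classification is not None:
        mask = classification.included_columns(class_filter)
    else:
        mask = ~(np.isin(mat, ["N", "-"]).any(axis=0))
    haps = ["".join(row) for row in mat[:, mask]]
    _, counts = np.unique(haps, return_counts=True)
    h = len(counts)
    p = counts / n
    hd = n / (n - 1) * (1.0 - float(np.sum(p**2)))
    return h, hd


def jukes_cantor(p: float) -> float:
    """JC69 distance K = -(3/4) ln(1 - 4p/3); raises on saturation."""
    if p < 0:
        raise ValueError("p must be non-negative")
    if p >= 0.75:
        raise SaturationError(f"p = {p:.4f} >= 0.75: JC correction undefined")
    return float(-0.75 * np.log1p(-4.0 * p / 3.0))


def divergence_jc(
    aln: HaplotypeAlignment,
    classification: Optional[SiteClassification] = None,
    class_filter: Optional[str] = None,
):
    """JC-corrected per-site divergence K to the outgroup for one class.

    The raw proportion p averages, over sample sequences, the per-site
    difference rate to the outgroup across included columns where the
    outgroup is called (A/C/G/T). Under synonymous/silent filters a coding
    difference contributes the synonymous weight of substituting the outgroup
    base into that sample sequence's codon; denominators are the class
    effective site counts restricted to outgroup-called columns.
    """
    out = aln.outgroup_array
    mat = aln.matrix
    n = aln.n
    out_called = np.isin(out, list("ACGT"))
    if classification is not None:
        weights = classification.site_weights(class_filter)
    else:
        if class_filter not in (None, "total"):
            raise ValueError("class filters require a SiteClassification")
        weights = (~(np.isin(mat, ["N", "-"]).any(axis=0))).astype(float)
    weights = weights * out_called
    sites = float(weights.sum())
    if sites <= 0:
        return UNDEFINED
    cols = np.nonzero(weights > 0)[0]
    aa_map = _codon_table(classification.genetic_code) if classification else None
    total_p = 0.0
    for row in range(n):
        num = 0.0
        for col in cols:
            if mat[row, col] == out[col]:
                continue
            if (
                classification is not None
                and classification.site_class[col] == int(SiteClass.CODING)
                and class_filter in ("synonymous", "nonsynonymous", "silent")
            ):
                triple, pos, strand, _ = classification.codon_map[col]
                forward = strand == "+"
                codon = [_oriented_base(mat[row, c], forward) for c in triple]
                mut = codon.copy()
                mut[pos] = _oriented_base(out[col], forward)
                aa1 = aa_map.get("".join(codon), "*")
                aa2 = aa_map.get("".join(mut), "*")
                syn = 1.0 if (aa1 == aa2 and aa1 != "*") else 0.0
                num += syn if class_filter in ("synonymous", "silent") else 1.0 - syn
            else:
                num += weights[col]
        total_p += num / sites
    p = total_p / n
    return jukes_cantor(p)


# ---------------------------------------------------------------------------
# NG86 codon-pair difference counting


_PATH_CACHE: dict[tuple[str, str, int], tuple[float, float]] = {}


def codon_pair_diffs(c1: str, c2: str, genetic_code: int = 1) -> tuple[float, float]:
    """(Sd, Nd): NG86 synonymous/nonsynonymous differences between two codons.

    All shortest mutational pathways are weighted equally; pathways passing
    through a stop codon are discarded (if every pathway does, all are kept
    and stop steps count as nonsynonymous).
    """
    key = (c1, c2, genetic_code)
    if key in _PATH_CACHE:
        return _PATH_CACHE[key]
    aa_map = _codon_table(genetic_code)
    diffs = [i for i in range(3) if c1[i] != c2[i]]
    if not diffs:
        _PATH_CACHE[key] = (0.0, 0.0)
        return 0.0, 0.0

    def walk(order):
        cur = c1
        sd = nd = 0.0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            aa_cur, aa_nxt = aa_map.get(cur, "*"), aa_map.get(nxt, "*")
            if aa_nxt == "*" and nxt != c2:
                blocked = True
            if aa_cur == aa_nxt and aa_cur != "*":
                sd += 1.0
            else:
                nd += 1.0
            cur = nxt
        return sd, nd, blocked

    results = [walk(order) for order in itertools.permutations(diffs)]
    open_paths = [(s, d) for s, d, b in results if not b]
    if not open_paths:
        open_paths = [(s, d) for s, d, _ in results]
    sd = float(np.mean([s for s, _ in open_paths]))
    nd = float(np.mean([d for _, d in open_paths]))
    _PATH_CACHE[key] = (sd, nd)
    return sd, nd


@dataclass
class KaKsResult:
    Ka: object  # float or UndefinedStatistic
    Ks: object
    omega: object
    Sd: float
    Nd: float
    syn_sites: float
    nonsyn_sites: float
    codons_used: int
    codons_skipped: int


def ka_ks_ng86(
    aln: HaplotypeAlignment,
    classification: SiteClassification,
    gene: Optional[str] = None,
) -> KaKsResult:
    """NG86 Ka/Ks between the sample and the outgroup, JC-corrected.

    Counts are averaged over sample sequences. Codons with a gap/N/stop in
    either sequence are skipped. omega is flagged undefined when Ks = 0 (or
    either distance is undefined).
    """
    out = aln.outgroup_array
    mat = aln.matrix
    aa_map = _codon_table(classification.genetic_code)
    triples = {}
    for col, (triple, pos, strand, g) in classification.codon_map.items():
        if gene is None or g == gene:
            triples[triple] = strand
    if not triples:
        return KaKsResult(UNDEFINED, UNDEFINED, UNDEFINED, 0, 0, 0, 0, 0, 0)

    sd_t = nd_t = ss_t = ns_t = 0.0
    used = skipped = 0
    n = aln.n
    for triple, strand in sorted(triples.items()):
        forward = strand == "+"
        out_codon = "".join(_oriented_base(out[c], forward) for c in triple)
        if any(b not in "ACGT" for b in out_codon) or aa_map.get(out_codon, "*") == "*":
            skipped += 1
            continue
        used += 1
        s_out = sum(codon_syn_fractions(out_codon, classification.genetic_code))
        for row in range(n):
            codon = "".join(_oriented_base(mat[row, c], forward) for c in triple)
            s_row = sum(codon_syn_fractions(codon, classification.genetic_code))
            sd, nd = codon_pair_diffs(codon, out_codon, classification.genetic_code)
            sd_t += sd / n
            nd_t += nd / n
            ss_t += (s_row + s_out) / 2.0 / n
            ns_t += (3.0 - (s_row + s_out) / 2.0) / n
    if used == 0:
        return KaKsResult(UNDEFINED, UNDEFINED, UNDEFINED, 0, 0, 0, 0, 0, skipped)

    def jc_or_undefined(d, sites):
        if sites <= 0:
            return UNDEFINED
        try:
            return jukes_cantor(d / sites)
        except SaturationError:
            return UNDEFINED
    ks = jc_or_undefined(sd_t, ss_t)
    ka = jc_or_undefined(nd_t, ns_t)
    if isinstance(ks, UndefinedStatistic) or isinstance(ka, UndefinedStatistic) or ks == 0:
        omega = UNDEFINED
    else:
        omega = ka / ks
    return KaKsResult(
        Ka=ka,
        Ks=ks,
        omega=omega,
        Sd=sd_t,
        Nd=nd_t,
        syn_sites=ss_t,
        nonsyn_sites=ns_t,
        codons_used=used,
        codons_skipped=skipped,
    )


@dataclass
class SummaryStatistics:
    """Per-region summary mirroring a polymorphism/divergence table row block."""

    region_id: str
    n: int
    sites: dict = field(default_factory=dict)
    S: dict = field(default_factory=dict)
    singletons: dict = field(default_factory=dict)
    pi: dict = field(default_factory=dict)
    K: dict = field(default_factory=dict)
    theta_W: object = None
    theta_L: object = None
    h: int = 0
    Hd: float = 0.0
    Ka: object = None
    Ks: object = None
    omega: object = None


DEFAULT_CLASSES = ("intronic", "synonymous", "silent", "nonsynonymous", "total")


def summarize_region(
    aln: HaplotypeAlignment,
    classification: SiteClassification,
    classes=DEFAULT_CLASSES,
) -> SummaryStatistics:
    """One-stop per-region summary (S, pi, h, Hd, K, Ka/Ks, theta estimators)."""
    table = variant_table(aln, classification, polarize=aln.has_outgroup)
    stats = SummaryStatistics(region_id=aln.region_id, n=aln.n)
    for cf in classes:
        stats.sites[cf] = classification.counts[cf]
        stats.S[cf], stats.singletons[cf] = segregating_sites(table, cf)
        stats.pi[cf] = nucleotide_diversity(aln, classification, cf, table=table)
        if aln.has_outgroup:
            try:
                stats.K[cf] = divergence_jc(aln, classification, cf)
            except SaturationError:
                stats.K[cf] = UNDEFINED
    stats.h, stats.Hd = haplotype_statistics(aln, classification)
    total_sites = classification.counts["total"]
    if total_sites > 0:
        stats.theta_W = watterson_theta(table.S, aln.n, total_sites)
        if aln.has_outgroup:
            sfs = SiteFrequencySpectrum.from_table(table)
            if sfs.S:
                _, stats.theta_L = theta_estimators(sfs, total_sites)
            else:
                stats.theta_L = 0.0
    if aln.has_outgroup and classification.codon_map:
        kk = ka_ks_ng86(aln, classification)
        stats.Ka, stats.Ks, stats.omega = kk.Ka, kk.Ks, kk.omega
    return stats
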