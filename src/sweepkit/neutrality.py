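"""Frequency-spectrum and polymorphism-divergence neutrality tests.

Frequency-spectrum tests: Tajima's D (folded data suffice) and the
normalized Fay-Wu H (Zeng et al. normalization; requires an outgroup-
polarized unfolded SFS). Their null distributions come from coalescent
simulation (`sweepkit.coalsim`); this module computes only the statistics
and analytic building blocks.

Polymorphism-divergence tests: the McDonald-Kreitman 2x2 Fisher exact
contrast of synonymous/nonsynonymous polymorphic vs fixed changes, and the
multilocus HKA test fitting per-locus population mutation parameters and a
common divergence time by moment equations, with a chi-square and an
optional parametric-bootstrap (coalescent) p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

from sweepkit._util import UNDEFINED, harmonic, harmonic2
from sweepkit.diversity import SiteFrequencySpectrum


def tajima_constants(n: int) -> dict[str, float]:
    """The a1, a2, b1, b2, c1, c2, e1, e2 constants of Tajima's D."""
    if n < 4:
        raise ValueError("Tajima's D requires n >= 4")
    a1 = harmonic(n)
    a2 = harmonic2(n)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return dict(a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2)


def tajima_D(S: int, pi_count: float, n: int):
    """Tajima's D from S and the mean pairwise difference count (per locus).

    D = (pi - S/a1) / sqrt(e1 S + e2 S(S-1)). Returns an UndefinedStatistic
    when S = 0.
    """
    if S == 0:
        return UNDEFINED
    c = tajima_constants(n)
    var = c["e1"] * S + c["e2"] * S * (S - 1)
    return float((pi_count - S / c["a1"]) / np.sqrt(var))


def fay_wu_H_normalized(sfs: SiteFrequencySpectrum):
    """Normalized Fay-Wu H from the unfolded SFS (Zeng et al. normalization).

    H = (theta_pi - theta_L) / sqrt(Var), with the variance evaluated at
    theta_hat = theta_W (per locus) and theta_hat^2 = S(S-1)/(a_n^2 + b_n):

        Var = theta (n-2)/(6(n-1))
            + theta^2 [18 n^2 (3n+2) b_{n+1} - (88 n^3 + 9 n^2 - 13 n + 6)]
              / (9 n (n-1)^2)

    where b_m = sum_{i=1}^{m-1} 1/i^2. Returns UndefinedStatistic when S = 0.
    """
    n = sfs.n
    S = sfs.S
    if S == 0:
        return UNDEFINED
    if n < 3:
        raise ValueError("normalized H requires n >= 3")
    a_n = harmonic(n)
    b_n = harmonic2(n)
    b_n1 = harmonic2(n + 1)
    theta_w = S / a_n
    theta_sq = S * (S - 1) / (a_n**2 + b_n)
    var = theta_w * (n - 2) / (6.0 * (n - 1)) + theta_sq * (
        18.0 * n**2 * (3 * n + 2) * b_n1 - (88.0 * n**3 + 9 * n**2 - 13 * n + 6)
    ) / (9.0 * n * (n - 1) ** 2)
    num = sfs.theta_pi_count() - sfs.theta_L_count()
    return float(num / np.sqrt(var))


# ---------------------------------------------------------------------------
# McDonald-Kreitman


@dataclass
class MKResult:
    Dn: int
    Ds: int
    Pn: int
    Ps: int
    p_value: float
    odds_ratio: float
    degenerate: bool
    lineage_specific: bool = False


def mk_test(
    Pn: int, Ps: int, Dn: int, Ds: int, lineage_specific: bool = False
) -> MKResult:
    """McDonald-Kreitman 2x2 test: polymorphic vs fixed, nonsyn vs syn.

    Two-tailed Fisher exact p-value by summing hypergeometric point
    probabilities <= the observed one. A zero margin makes the table
    degenerate: p = 1 with a flag.
    """
    for v in (Pn, Ps, Dn, Ds):
        if v < 0:
            raise ValueError("MK counts must be non-negative")
    table = np.array([[Dn, Ds], [Pn, Ps]])
    degenerate = (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any()
    if degenerate:
        p = 1.0
        odds = np.nan
    else:
        odds, p = stats.fisher_exact(table, alternative="two-sided")
    return MKResult(
        Dn=Dn,
        Ds=Ds,
        Pn=Pn,
        Ps=Ps,
        p_value=float(p),
        odds_ratio=float(odds) if np.isfinite(odds) else float("inf"),
        degenerate=bool(degenerate),
        lineage_specific=lineage_specific,
    )


def count_fixed_differences(aln, classification) -> dict[str, int]:
    """Count fixed synonymous/nonsynonymous differences to the outgroup.

    A fixed difference is an included column where the sample is monomorphic
    and the outgroup carries a different called base; sites polymorphic in
    the sample are excluded from the fixed class. Coding changes are
    classified by substituting the outgroup base into the sample codon.
    """
    from sweepkit.regions import SiteClass, _codon_table, _oriented_base

    mat = aln.matrix
    out = aln.outgroup_array
    aa_map = _codon_table(classification.genetic_code)
    counts = {"synonymous": 0, "nonsynonymous": 0, "noncoding": 0}
    for col in np.nonzero(classification.site_class != int(SiteClass.EXCLUDED))[0]:
        col = int(col)
        column = mat[:, col]
        if len(set(column)) != 1:
            continue  # polymorphic: excluded from the fixed class
        if out[col] not in "ACGT" or out[col] == column[0]:
            continue
        if classification.site_class[col] == int(SiteClass.CODING):
            triple, pos, strand, _ = classification.codon_map[col]
            forward = strand == "+"
            codon = [_oriented_base(mat[0, c], forward) for c in triple]
            mut = codon.copy()
            mut[pos] = _oriented_base(out[col], forward)
            aa1 = aa_map.get("".join(codon), "*")
            aa2 = aa_map.get("".join(mut), "*")
            if aa1 == aa2 and aa1 != "*":
                counts["synonymous"] += 1
            else:
                counts["nonsynonymous"] += 1
        else:
            counts["noncoding"] += 1
    return counts


def mk_test_from_region(
    aln,
    classification,
    table=None,
    second_outgroup: Optional[str] = None,
) -> MKResult:
    """Build the MK table from a classified region and run the test.

    With `second_outgroup` (an aligned sequence string), fixed changes are
    polarized by parsimony and only those specific to the focal lineage
    (second outgroup agrees with the first) are counted.
    """
    from sweepkit.regions import variant_table

    if table is None:
        table = variant_table(aln, classification)
    pn = int((table.df["change_type"] == "nonsynonymous").sum())
    ps = int((table.df["change_type"] == "synonymous").sum())
    fixed = count_fixed_differences(aln, classification)
    dn, ds = fixed["nonsynonymous"], fixed["synonymous"]
    lineage = second_outgroup is not None
    if lineage:
        out2 = np.array(list(second_outgroup.upper()), dtype="<U1")
        if len(out2) != aln.length:
            raise ValueError("second outgroup length mismatch")
        dn, ds = _lineage_specific_fixed(aln, classification, out2)
    return mk_test(Pn=pn, Ps=ps, Dn=dn, Ds=ds, lineage_specific=lineage)


def _lineage_specific_fixed(aln, classification, out2: np.ndarray) -> tuple[int, int]:
    from sweepkit.regions import SiteClass, _codon_table, _oriented_base

    mat = aln.matrix
    out = aln.outgroup_array
    aa_map = _codon_table(classification.genetic_code)
    dn = ds = 0
    for col in np.nonzero(classification.site_class == int(SiteClass.CODING))[0]:
        col = int(col)
        column = mat[:, col]
        if len(set(column)) != 1:
            continue
        b_focal, b_out, b_out2 = column[0], out[col], out2[col]
        if b_out not in "ACGT" or b_out2 not in "ACGT":
            continue
        # focal-lineage fixation: both outgroups share the ancestral state
        if b_out != b_out2 or b_focal == b_out:
            continue
        triple, pos, strand, _ = classification.codon_map[col]
        forward = strand == "+"
        codon = [_oriented_base(mat[0, c], forward) for c in triple]
        mut = codon.copy()
        mut[pos] = _oriented_base(b_out, forward)
        aa1 = aa_map.get("".join(codon), "*")
        aa2 = aa_map.get("".join(mut), "*")
        if aa1 == aa2 and aa1 != "*":
            ds += 1
        else:
            dn += 1
    return dn, ds


# ---------------------------------------------------------------------------
# Multilocus HKA


@dataclass
class HKALocus:
    """Observed polymorphism and divergence for one locus.

    S_obs: segregating sites; D_obs: divergence count (differences to the
    outgroup over sites_div); sites_poly/sites_div: effective site counts;
    n: sample size; inheritance_factor: 1 autosomal, 3/4 X-linked.
    """

    name: str
    S_obs: float
    D_obs: float
    sites_poly: float
    sites_div: float
    n: int
    inheritance_factor: float = 1.0


@dataclass
class HKAResult:
    X2: float
    df: int
    p_chisq: float
    theta_hat: np.ndarray  # per-locus theta per site (autosomal-equivalent)
    T_hat: float
    expected_S: np.ndarray
    expected_D: np.ndarray
    var_S: np.ndarray
    var_D: np.ndarray
    p_sim: Optional[float] = None
    sim_reps: int = 0


class HKAFitError(RuntimeError):
    pass


def _hka_fit(loci: Sequence[HKALocus]) -> tuple[np.ndarray, float]:
    """Solve the moment equations for per-locus theta and common T.

    With f the inheritance factor and theta the autosomal-equivalent
    per-locus population mutation parameter (x sites):
    E[S_i] = f_i theta_i a_{n_i};  E[D_i] = theta_i (T + f_i).
    Given T, theta_i = (S_i + D_i) / (f_i a_{n_i} + T + f_i); T solves
    sum_i D_i = sum_i theta_i (T + f_i).
    """
    S = np.array([l.S_obs for l in loci], dtype=float)
    D = np.array([l.D_obs for l in loci], dtype=float)
    a = np.array([harmonic(l.n) for l in loci])
    f = np.array([l.inheritance_factor for l in loci])

    def theta_of(T):
        return (S + D) / (f * a + T + f)

    def g(T):
        th = theta_of(T)
        return float(np.sum(D) - np.sum(th * (T + f)))

    lo, hi = 1e-9, 1e9
    glo, ghi = g(lo), g(hi)
    if not np.isfinite(glo) or not np.isfinite(ghi) or glo * ghi > 0:
        raise HKAFitError(
            f"moment system has no root in ({lo}, {hi}): g({lo})={glo}, g({hi})={ghi}"
        )
    T = optimize.brentq(g, lo, hi, xtol=1e-12, rtol=1e-12)
    return theta_of(T), float(T)


def hka_multilocus(
    loci: Sequence[HKALocus],
    sim_reps: int = 0,
    seed: Optional[int] = None,
) -> HKAResult:
    """Multilocus HKA test of polymorphism/divergence homogeneity.

    X2 sums, over loci, the squared deviations of S and D from their fitted
    neutral expectations scaled by the model variances (which include the
    ancestral-polymorphism contribution to divergence). p_chisq uses df =
    L - 1; sim_reps > 0 adds a parametric-bootstrap p-value from neutral
    coalescent replicates simulated at the fitted parameters and refitted.
    """
    loci = list(loci)
    if len(loci) < 2:
        raise ValueError("HKA requires at least 2 loci (df = L - 1 >= 1)")
    theta, T = _hka_fit(loci)
    X2, eS, eD, vS, vD = _hka_x2(loci, theta, T)
    df = len(loci) - 1
    p = float(stats.chi2.sf(X2, df))
    result = HKAResult(
        X2=X2,
        df=df,
        p_chisq=p,
        theta_hat=theta
        / np.array([l.sites_poly if l.sites_poly > 0 else 1.0 for l in loci]),
        T_hat=T,
        expected_S=eS,
        expected_D=eD,
        var_S=vS,
        var_D=vD,
    )
    if sim_reps > 0:
        rng = np.random.default_rng(seed)
        exceed = 0
        valid = 0
        for _ in range(sim_reps):
            sim = _hka_simulate(loci, theta, T, rng)
            try:
                th_s, T_s = _hka_fit(sim)
            except HKAFitError:
                continue
            x2_s, *_ = _hka_x2(sim, th_s, T_s)
            valid += 1
            if x2_s >= X2:
                exceed += 1
        result.p_sim = exceed / valid if valid else None
        result.sim_reps = valid
    return result


def _hka_x2(loci, theta, T):
    S = np.array([l.S_obs for l in loci], dtype=float)
    D = np.array([l.D_obs for l in loci], dtype=float)
    a = np.array([harmonic(l.n) for l in loci])
    b = np.array([harmonic2(l.n) for l in loci])
    f = np.array([l.inheritance_factor for l in loci])
    eS = f * theta * a
    vS = f * theta * a + (f * theta) ** 2 * b
    eD = theta * (T + f)
    vD = eD + (f * theta) ** 2
    X2 = float(np.sum((S - eS) ** 2 / vS) + np.sum((D - eD) ** 2 / vD))
    return X2, eS, eD, vS, vD


def _hka_simulate(loci, theta, T, rng) -> list[HKALocus]:
    """One neutral replicate of every locus at the fitted parameters."""
    from sweepkit.coalsim import _coalescent_intervals, DemographyModel

    sim = []
    for l, th in zip(loci, theta):
        f = l.inheritance_factor
        dem = DemographyModel.snm(inheritance_factor=f)
        # tree length in 4N0 units; the inheritance factor enters through the
        # demography's coalescence-rate scaling, so E[len] = f * a_n
        _, tree_len, _ = _coalescent_intervals(rng, l.n, dem)
        S_sim = rng.poisson(th * tree_len)
        t_anc = rng.exponential(f)  # ancestral coalescent, mean f in 2N0 units
        D_sim = rng.poisson(th * (T + t_anc))
        sim.append(
            HKALocus(
                name=l.name,
                S_obs=float(S_sim),
                D_obs=float(D_sim),
                sites_poly=l.sites_poly,
                sites_div=l.sites_div,
                n=l.n,
                inheritance_factor=f,
            )
        )
    return sim
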