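"""Synthetic region fixtures: alignments + annotation + outgroup with truth.

Generates alignments that emulate multi-kb resequenced gene regions in a
derived Drosophila population: 10-12 haplotypes over 0.7-7.5 kb of mixed
coding/noncoding structure, silent diversity in the 0.003-0.011 per-site
range, silent divergence to a single outgroup sequence of 0.05-0.16, an
optional excluded spacer, purifying selection emulated by suppressing a
fraction of nonsynonymous mutations, and an optional injected selective
sweep. Every fixture carries a truth record (planted theta, per-class
mutation bookkeeping, sweep parameters) so pipeline results can be checked
against what was planted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from sweepkit import coalsim
from sweepkit.coalsim import DemographyModel, SimulationConfig
from sweepkit.diversity import SiteFrequencySpectrum
from sweepkit.neutrality import fay_wu_H_normalized, tajima_D
from sweepkit.regions import (
    Feature,
    HaplotypeAlignment,
    RegionAnnotation,
    classify_sites,
    write_gff3,
    _codon_table,
)

_NONSTOP_CODONS = None


def _nonstop_codons(genetic_code: int = 1) -> list[str]:
    global _NONSTOP_CODONS
    if _NONSTOP_CODONS is None:
        aa = _codon_table(genetic_code)
        _NONSTOP_CODONS = sorted(c for c, a in aa.items() if a != "*")
    return _NONSTOP_CODONS


@dataclass
class RegionFixtureSpec:
    """Recipe for one synthetic region.

    layout: sequence of (feature_type, length[, gene]) tuples laid end to
    end; CDS lengths of one gene must sum to a multiple of 3. constraint:
    fraction of nonsynonymous mutations suppressed (1.0 = none survive).
    sweep: optional (alpha, X) injected instantaneous sweep at the present.
    """

    region_id: str
    n: int
    layout: Sequence[tuple]
    target_silent_pi: float
    target_silent_K: float
    constraint: float = 0.8
    rho_per_site: float = 0.0
    demography: Optional[DemographyModel] = None
    sweep: Optional[tuple[float, float]] = None
    epsilon: float = 1e-6

    def __post_init__(self):
        if not (0.0 <= self.target_silent_pi <= 0.05):
            raise ValueError("target silent pi outside [0, 0.05]")
        if not (0.0 <= self.target_silent_K <= 0.3):
            raise ValueError("target silent K outside [0, 0.3]")
        if not (0.0 <= self.constraint <= 1.0):
            raise ValueError("constraint must lie in [0, 1]")
        if self.n < 2:
            raise ValueError("n must be >= 2")

    @property
    def L(self) -> int:
        return int(sum(item[1] for item in self.layout))

    def annotation(self) -> RegionAnnotation:
        feats = []
        pos = 0
        for item in self.layout:
            ftype, length = item[0], int(item[1])
            gene = item[2] if len(item) > 2 else ""
            feats.append(
                Feature(ftype=ftype, start=pos, end=pos + length, strand="+",
                        phase=0, gene=gene)
            )
            pos += length
        return RegionAnnotation(features=feats)


@dataclass
class RegionFixture:
    """A generated region: alignment, annotation, and the planted truth."""

    alignment: HaplotypeAlignment
    annotation: RegionAnnotation
    truth: dict = field(default_factory=dict)

    def write(self, directory) -> dict[str, str]:
        import os

        os.makedirs(directory, exist_ok=True)
        rid = self.alignment.region_id
        fasta = os.path.join(directory, f"{rid}.fasta")
        gff = os.path.join(directory, f"{rid}.gff3")
        truth = os.path.join(directory, f"{rid}.truth.json")
        with open(fasta, "w") as fh:
            for sid, seq in zip(self.alignment.sample_ids, self.alignment.sequences):
                fh.write(f">{sid}\n{seq}\n")
            if self.alignment.has_outgroup:
                fh.write(
                    f">{self.alignment.outgroup_id}\n{self.alignment.outgroup_sequence}\n"
                )
        write_gff3(self.annotation, gff, seqid=rid)
        with open(truth, "w") as fh:
            json.dump(self.truth, fh, indent=1, default=float)
        return {"fasta": fasta, "gff": gff, "truth": truth}


def _ancestral_sequence(rng, ann: RegionAnnotation, L: int) -> list[str]:
    """Random ancestral sequence with stop-free open reading frames."""
    seq = [rng.choice(list("ACGT")) for _ in range(L)]
    codons = _nonstop_codons()
    for gene, feats in ann.cds_by_gene().items():
        cols = []
        for f in sorted(feats, key=lambda f: f.start):
            cols.extend(range(f.start, f.end))
        if len(cols) % 3 != 0:
            raise ValueError(f"CDS of gene {gene!r} not a multiple of 3")
        for i in range(0, len(cols), 3):
            codon = codons[int(rng.integers(len(codons)))]
            for j in range(3):
                seq[cols[i + j]] = codon[j]
    return seq


def _tune_theta(rng, spec: RegionFixtureSpec, silent_sites: float,
                pilot_reps: int = 50, tol: float = 0.15) -> float:
    """Bisection of theta against realized mean pilot silent pi."""
    target = spec.target_silent_pi
    if target == 0:
        return 0.0
    dem = spec.demography or DemographyModel.snm()
    L_eff = max(int(round(silent_sites)), 1)
    lo, hi = target / 10.0, target * 10.0

    def realized(theta: float) -> float:
        cfg = SimulationConfig(n=spec.n, L=L_eff, theta=theta, reps=pilot_reps)
        reps = coalsim.simulate_neutral(cfg, dem, rng=rng)
        return float(np.mean(reps.pi_counts()) / L_eff)

    theta = target
    for _ in range(8):
        r = realized(theta)
        if r > 0 and abs(r - target) / target <= tol:
            return theta
        if r < target:
            lo = theta
        else:
            hi = theta
        theta = (lo + hi) / 2.0
    return theta


def generate_region_fixture(spec: RegionFixtureSpec, seed: int) -> RegionFixture:
    """Generate one region fixture (alignment + outgroup + truth record).

    Sample haplotypes descend from a coalescent genealogy (neutral or
    sweep-conditioned) at a theta tuned so realized silent diversity matches
    the target; the outgroup sits on a single unbroken divergence branch
    whose substitution probability is the JC inversion of the target silent
    K. Nonsynonymous mutations are suppressed with probability `constraint`;
    mutations creating stop codons are always discarded.
    """
    rng = np.random.default_rng(seed)
    ann = spec.annotation()
    L = spec.L
    dem = spec.demography or DemographyModel.snm()
    anc = _ancestral_sequence(rng, ann, L)
    aa_map = _codon_table(1)

    # column -> (codon column triple, position) for effect classification
    codon_of: dict[int, tuple[tuple[int, int, int], int]] = {}
    site_kind = ["intergenic"] * L
    for f in ann.features:
        for c in range(f.start, f.end):
            if f.ftype == "CDS":
                site_kind[c] = "coding"
            elif f.ftype == "intron":
                site_kind[c] = "intronic"
            elif f.ftype == "spacer":
                site_kind[c] = "spacer"
    for gene, feats in ann.cds_by_gene().items():
        cols = []
        for f in sorted(feats, key=lambda f: f.start):
            cols.extend(range(f.start, f.end))
        for i in range(0, len(cols), 3):
            triple = tuple(cols[i : i + 3])
            for j in range(3):
                codon_of[triple[j]] = (triple, j)

    def classify_change(col: int, new_base: str) -> str:
        """'silent' | 'nonsynonymous' | 'stop' for a change on the ancestor."""
        if site_kind[col] != "coding":
            return "silent"
        triple, pos = codon_of[col]
        codon = "".join(anc[c] for c in triple)
        mut = codon[:pos] + new_base + codon[pos + 1 :]
        aa1, aa2 = aa_map.get(codon, "*"), aa_map.get(mut, "*")
        if aa2 == "*":
            return "stop"
        return "silent" if aa1 == aa2 else "nonsynonymous"

    # pilot-tune theta against silent pi (silent-site mutation supply is
    # unaffected by the nonsynonymous suppression)
    silent_sites_rough = sum(
        1 for k in site_kind if k in ("intronic", "intergenic")
    ) + 0.25 * sum(1 for k in site_kind if k == "coding")
    theta = _tune_theta(rng, spec, silent_sites_rough)

    cfg = SimulationConfig(
        n=spec.n, L=L, theta=theta, rho_per_site=spec.rho_per_site, reps=1
    )
    seqs = [list(anc) for _ in range(spec.n)]
    occupied = set()
    counts = {"silent": 0, "nonsynonymous": 0, "suppressed": 0, "stop_dropped": 0}
    bases = "ACGT"
    for start, width in cfg.windows():
        if spec.sweep is not None:
            from sweepkit.sweepscan import escape_probability

            alpha, X = spec.sweep
            p = escape_probability(
                abs(start + width / 2.0 - X), spec.rho_per_site, alpha, spec.epsilon
            )
            branches, length, _ = coalsim._sweep_genealogy(rng, spec.n, dem, p, 0.0)
        else:
            branches, length, _ = coalsim._neutral_genealogy(rng, spec.n, dem)
        if length <= 0 or theta <= 0:
            continue
        S_w = rng.poisson(theta * width * length)
        if S_w == 0:
            continue
        masks = coalsim._place_mutations_masks(rng, branches, S_w)
        for mask in masks:
            col = None
            for _try in range(20):  # infinite-sites on discrete columns
                cand = int(start + rng.integers(int(round(width))))
                if cand not in occupied and cand < L:
                    col = cand
                    break
            if col is None:
                continue
            old = anc[col]
            others = [b for b in bases if b != old]
            new = others[int(rng.integers(3))]
            kind = classify_change(col, new)
            if kind == "stop":
                counts["stop_dropped"] += 1
                continue
            if kind == "nonsynonymous" and rng.random() < spec.constraint:
                counts["suppressed"] += 1
                continue
            occupied.add(col)
            counts[kind] += 1
            for leaf in range(spec.n):
                if mask >> leaf & 1:
                    seqs[leaf][col] = new

    # outgroup: JC substitution on a single unbroken divergence branch
    out = list(anc)
    div_counts = {"silent": 0, "nonsynonymous": 0, "suppressed": 0, "stop_dropped": 0}
    if spec.target_silent_K > 0:
        p_sub = 0.75 * -np.expm1(-4.0 * spec.target_silent_K / 3.0)
        hit = rng.random(L) < p_sub
        for col in np.nonzero(hit)[0]:
            col = int(col)
            old = anc[col]
            new = old
            while new == old:
                new = bases[int(rng.integers(4))]
            kind = classify_change(col, new)
            if kind == "stop":
                div_counts["stop_dropped"] += 1
                continue
            if kind == "nonsynonymous" and rng.random() < spec.constraint:
                div_counts["suppressed"] += 1
                continue
            div_counts[kind] += 1
            out[col] = new

    # spacer columns are masked so no statistic can span them
    for col, k in enumerate(site_kind):
        if k == "spacer":
            for s in seqs:
                s[col] = "N"
            out[col] = "N"

    aln = HaplotypeAlignment(
        region_id=spec.region_id,
        sample_ids=[f"{spec.region_id}_h{i + 1:02d}" for i in range(spec.n)],
        sequences=["".join(s) for s in seqs],
        outgroup_id="outgroup",
        outgroup_sequence="".join(out),
    )
    classification = classify_sites(aln, ann)
    truth = {
        "region_id": spec.region_id,
        "seed": int(seed),
        "n": spec.n,
        "L": L,
        "planted_theta_per_site": theta,
        "target_silent_pi": spec.target_silent_pi,
        "target_silent_K": spec.target_silent_K,
        "constraint": spec.constraint,
        "rho_per_site": spec.rho_per_site,
        "sweep": list(spec.sweep) if spec.sweep else None,
        "polymorphism_counts": counts,
        "divergence_counts": div_counts,
        "site_counts": {k: classification.counts[k] for k in classification.counts},
    }
    return RegionFixture(alignment=aln, annotation=ann, truth=truth)


def dilp_like_region_specs(
    demography: Optional[DemographyModel] = None,
    sweep_in_first: bool = True,
) -> list[RegionFixtureSpec]:
    """Four default fixtures emulating the studied region set.

    Lengths 7424/3201/2352/699 bp, n = 10 for the first and 12 elsewhere,
    silent pi targets 0.003-0.011, silent K targets 0.05-0.16, mixed
    coding/noncoding layouts (the third with an excluded ~390 bp spacer),
    genetic-map recombination rates, and an optional injected sweep in the
    large first region (which the sweep scan should then flag).
    """
    specs = [
        RegionFixtureSpec(
            region_id="regionA",
            n=10,
            layout=[
                ("flanking", 1200),
                ("CDS", 462, "gA1"),
                ("intergenic", 900),
                ("CDS", 210, "gA2"),
                ("intron", 73),
                ("CDS", 201, "gA2"),
                ("intergenic", 800),
                ("CDS", 360, "gA3"),
                ("intergenic", 700),
                ("CDS", 402, "gA4"),
                ("intergenic", 2116),
            ],
            target_silent_pi=0.003,
            target_silent_K=0.059,
            rho_per_site=0.063,
            sweep=(2000.0, 3712.0) if sweep_in_first else None,
            demography=demography,
        ),
        RegionFixtureSpec(
            region_id="regionB",
            n=12,
            layout=[
                ("flanking", 1300),
                ("CDS", 150, "gB1"),
                ("intron", 71),
                ("CDS", 171, "gB1"),
                ("intergenic", 1509),
            ],
            target_silent_pi=0.009,
            target_silent_K=0.051,
            rho_per_site=0.063,
            demography=demography,
        ),
        RegionFixtureSpec(
            region_id="regionC",
            n=12,
            layout=[
                ("flanking", 400),
                ("CDS", 150, "gC1"),
                ("spacer", 390),
                ("intron", 480),
                ("CDS", 171, "gC1"),
                ("intergenic", 761),
            ],
            target_silent_pi=0.004,
            target_silent_K=0.061,
            rho_per_site=0.047,
            demography=demography,
        ),
        RegionFixtureSpec(
            region_id="regionD",
            n=12,
            layout=[
                ("flanking", 100),
                ("CDS", 279, "gD1"),
                ("intron", 100),
                ("CDS", 123, "gD1"),
                ("intergenic", 97),
            ],
            target_silent_pi=0.011,
            target_silent_K=0.164,
            rho_per_site=0.058,
            demography=demography,
        ),
    ]
    return specs


def generate_background_loci(
    count: int,
    n: int = 12,
    L: int = 500,
    theta: float = 0.01,
    rho_per_site: float = 0.0,
    demography: Optional[DemographyModel] = None,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Multilocus neutral background distribution of D and H.

    Simulates `count` independent noncoding loci under a shared demography
    and returns per-locus S, Tajima's D and normalized Fay-Wu H, the
    empirical background against which region statistics can be ranked.
    """
    if count < 20:
        raise ValueError("background needs at least 20 loci")
    cfg = SimulationConfig(
        n=n, L=L, theta=theta, rho_per_site=rho_per_site, reps=count, seed=seed
    )
    reps = coalsim.simulate_neutral(cfg, demography)
    pi = reps.pi_counts()
    rows = []
    for r in range(count):
        cnt = reps.counts[r]
        sfs = SiteFrequencySpectrum.from_counts(n, cnt[(cnt >= 1) & (cnt <= n - 1)])
        S = sfs.S
        d = tajima_D(S, pi[r], n) if S else np.nan
        h = fay_wu_H_normalized(sfs) if S else np.nan
        rows.append(dict(locus=r, S=S, D=float(d) if S else np.nan,
                         H=float(h) if S else np.nan))
    return pd.DataFrame(rows)


def empirical_rank(stat_obs: float, background) -> tuple[float, bool]:
    """Percentile of an observed statistic in a background distribution.

    Returns (fraction of background values <= obs, flag for the bottom 5%).
    """
    vals = np.asarray(background, dtype=float)
    vals = vals[np.isfinite(vals)]
    if len(vals) == 0:
        raise ValueError("background distribution is empty")
    pct = float(np.mean(vals <= stat_obs))
    return pct, pct <= 0.05
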