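"""Aligned-region I/O, functional site classification, and variant polarization.

The unit of analysis is one resequenced genomic region: an aligned set of
within-species haplotypes (multi-FASTA), optionally one aligned outgroup
sequence, and a GFF3-like annotation assigning every alignment column to a
functional class (CDS, intron, intergenic/flanking, or an excluded spacer).

Coding columns receive fractional synonymous/nonsynonymous site weights by
Nei-Gojobori (1986) counting: at each codon position the synonymous fraction
is the number of the three possible point mutations that preserve the amino
acid, divided by three, averaged over the sample sequences' codons. Effective
per-class site counts are sums of these fractions and are therefore
non-integer for coding classes.

Coordinates are 0-based half-open internally; human-readable output is
1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Data import CodonTable

VALID_CHARS = set("ACGTN-")
# IUPAC ambiguity codes are accepted on input and normalized to N.
IUPAC_AMBIG = set("RYSWKMBDHV")

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N", "-": "-"}


class AlignmentShapeError(ValueError):
    """Sequences in one alignment do not all have the same length."""


class ContentError(ValueError):
    """A sequence contains characters outside the IUPAC nucleotide alphabet."""


class AnnotationError(ValueError):
    """Region annotation is inconsistent with the alignment (frame, bounds...)."""


class PolarizationError(ValueError):
    """Outgroup-based polarization requested but no outgroup is available."""


class SiteClass(IntEnum):
    CODING = 0
    INTRONIC = 1
    INTERGENIC = 2  # includes flanking
    EXCLUDED = 3


CLASS_NAMES = {
    SiteClass.CODING: "coding",
    SiteClass.INTRONIC: "intronic",
    SiteClass.INTERGENIC: "intergenic",
    SiteClass.EXCLUDED: "excluded",
}


@dataclass
class HaplotypeAlignment:
    """Aligned within-species sample plus optional aligned outgroup."""

    region_id: str
    sample_ids: list[str]
    sequences: list[str]
    outgroup_id: Optional[str] = None
    outgroup_sequence: Optional[str] = None

    def __post_init__(self):
        if len(self.sample_ids) != len(self.sequences):
            raise AlignmentShapeError("sample_ids and sequences differ in number")
        if self.n < 2:
            raise AlignmentShapeError("need at least 2 sample sequences")
        if len(set(self.sample_ids)) != self.n:
            raise AlignmentShapeError("sample_ids are not unique")
        lengths = {len(s) for s in self.sequences}
        if self.outgroup_sequence is not None:
            lengths.add(len(self.outgroup_sequence))
        if len(lengths) != 1:
            raise AlignmentShapeError(f"unequal aligned lengths: {sorted(lengths)}")

    @property
    def n(self) -> int:
        return len(self.sequences)

    @property
    def length(self) -> int:
        return len(self.sequences[0])

    @property
    def has_outgroup(self) -> bool:
        return self.outgroup_sequence is not None

    _matrix_cache: Optional[np.ndarray] = field(default=None, repr=False, compare=False)

    @property
    def matrix(self) -> np.ndarray:
        """Sample sequences as an (n, length) array of single characters."""
        if self._matrix_cache is None:
            self._matrix_cache = np.array(
                [list(s) for s in self.sequences], dtype="<U1"
            )
        return self._matrix_cache

    @property
    def outgroup_array(self) -> np.ndarray:
        if not self.has_outgroup:
            raise PolarizationError("alignment has no outgroup sequence")
        return np.array(list(self.outgroup_sequence), dtype="<U1")


@dataclass(frozen=True)
class Feature:
    ftype: str  # CDS | intron | intergenic | flanking | spacer
    start: int  # 0-based half-open on alignment columns
    end: int
    strand: str = "+"
    phase: int = 0
    gene: str = ""


@dataclass
class RegionAnnotation:
    """Functional layout of one aligned region (0-based half-open columns)."""

    features: list[Feature]

    def validate(self, length: int) -> None:
        for f in self.features:
            if not (0 <= f.start < f.end <= length):
                raise AnnotationError(
                    f"feature {f.ftype} [{f.start},{f.end}) outside [0,{length})"
                )

    def cds_by_gene(self) -> dict[str, list[Feature]]:
        genes: dict[str, list[Feature]] = {}
        for f in self.features:
            if f.ftype == "CDS":
                genes.setdefault(f.gene or "gene", []).append(f)
        return genes


@dataclass
class SiteClassification:
    """Per-column functional class with fractional NG86 site counts."""

    length: int
    site_class: np.ndarray  # int codes per column (SiteClass values)
    syn_fraction: np.ndarray  # fraction in [0,1] at coding columns, nan elsewhere
    exclusion_reasons: dict[int, str]
    counts: dict[str, float]
    # per coding column: (codon alignment-column triple in reading order,
    # position within codon, strand, gene)
    codon_map: dict[int, tuple[tuple[int, int, int], int, str, str]]
    genetic_code: int = 1

    def included_columns(self, class_filter: Optional[str] = None) -> np.ndarray:
        """Boolean mask of columns belonging to the requested class.

        class_filter: None or 'total' (all non-excluded), 'coding', 'intronic',
        'intergenic', 'noncoding', 'silent' (non-coding + coding; coding columns
        then carry fractional weight via syn_fraction), 'synonymous',
        'nonsynonymous'.
        """
        cls = self.site_class
        if class_filter in (None, "total"):
            return cls != SiteClass.EXCLUDED
        if class_filter == "coding":
            return cls == SiteClass.CODING
        if class_filter == "intronic":
            return cls == SiteClass.INTRONIC
        if class_filter == "intergenic":
            return cls == SiteClass.INTERGENIC
        if class_filter == "noncoding":
            return (cls == SiteClass.INTRONIC) | (cls == SiteClass.INTERGENIC)
        if class_filter in ("silent", "synonymous", "nonsynonymous"):
            # Coding columns participate with fractional weight; the mask
            # includes them, weighting is the caller's concern (site_weights).
            if class_filter == "silent":
                return cls != SiteClass.EXCLUDED
            return cls == SiteClass.CODING
        raise ValueError(f"unknown class filter {class_filter!r}")

    def site_weights(self, class_filter: Optional[str] = None) -> np.ndarray:
        """Per-column effective-site weight under the requested class."""
        w = np.zeros(self.length)
        cls = self.site_class
        coding = cls == SiteClass.CODING
        noncoding = (cls == SiteClass.INTRONIC) | (cls == SiteClass.INTERGENIC)
        if class_filter in (None, "total"):
            w[coding | noncoding] = 1.0
        elif class_filter == "coding":
            w[coding] = 1.0
        elif class_filter == "intronic":
            w[cls == SiteClass.INTRONIC] = 1.0
        elif class_filter == "intergenic":
            w[cls == SiteClass.INTERGENIC] = 1.0
        elif class_filter == "noncoding":
            w[noncoding] = 1.0
        elif class_filter == "synonymous":
            w[coding] = self.syn_fraction[coding]
        elif class_filter == "nonsynonymous":
            w[coding] = 1.0 - self.syn_fraction[coding]
        elif class_filter == "silent":
            w[noncoding] = 1.0
            w[coding] = self.syn_fraction[coding]
        else:
            raise ValueError(f"unknown class filter {class_filter!r}")
        return w

    def class_name(self, col: int) -> str:
        return CLASS_NAMES[SiteClass(self.site_class[col])]


def read_alignment(
    path,
    outgroup_id: Optional[str] = None,
    region_id: Optional[str] = None,
) -> HaplotypeAlignment:
    """Read an aligned multi-FASTA; split off the outgroup record if named.

    Lowercase is normalized to uppercase and IUPAC ambiguity codes to N.
    Raises AlignmentShapeError / ContentError / KeyError on malformed input.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ContentError(f"no FASTA records in {path}")
    ids, seqs = [], []
    for rec in records:
        s = str(rec.seq).upper()
        bad = set(s) - VALID_CHARS - IUPAC_AMBIG
        if bad:
            raise ContentError(f"record {rec.id}: non-IUPAC characters {sorted(bad)}")
        for c in IUPAC_AMBIG:
            if c in s:
                s = s.replace(c, "N")
        ids.append(rec.id)
        seqs.append(s)
    out_seq = None
    if outgroup_id is not None:
        if outgroup_id not in ids:
            raise KeyError(f"outgroup id {outgroup_id!r} not found in {path}")
        i = ids.index(outgroup_id)
        out_seq = seqs.pop(i)
        ids.pop(i)
    if len(seqs) < 2:
        raise AlignmentShapeError("fewer than 2 sample records after removing outgroup")
    return HaplotypeAlignment(
        region_id=region_id or (str(path).rsplit("/", 1)[-1].rsplit(".", 1)[0]),
        sample_ids=ids,
        sequences=seqs,
        outgroup_id=outgroup_id,
        outgroup_sequence=out_seq,
    )


_GFF_TYPE_MAP = {
    "cds": "CDS",
    "intron": "intron",
    "intergenic": "intergenic",
    "flanking": "flanking",
    "region": "intergenic",
    "spacer": "spacer",
}


def read_gff3(path) -> RegionAnnotation:
    """Parse a minimal GFF3 (CDS/intron/intergenic/flanking/spacer features).

    GFF3 is 1-based inclusive; converted to 0-based half-open alignment
    columns. The CDS phase column is honored.
    """
    feats: list[Feature] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 8:
                raise AnnotationError(f"malformed GFF3 line: {line!r}")
            _, _, ftype, start, end, _, strand, phase = parts[:8]
            key = ftype.lower()
            if key not in _GFF_TYPE_MAP:
                continue
            gene = ""
            if len(parts) >= 9:
                for kv in parts[8].split(";"):
                    if "=" in kv:
                        k, v = kv.split("=", 1)
                        if k in ("ID", "Parent", "gene_id", "gene"):
                            gene = v
                            break
            feats.append(
                Feature(
                    ftype=_GFF_TYPE_MAP[key],
                    start=int(start) - 1,
                    end=int(end),
                    strand=strand if strand in "+-" else "+",
                    phase=int(phase) if phase.isdigit() else 0,
                    gene=gene,
                )
            )
    return RegionAnnotation(features=feats)


def write_gff3(ann: RegionAnnotation, path, seqid: str = "region") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in ann.features:
            attrs = f"ID={f.gene}" if f.gene else "."
            phase = str(f.phase) if f.ftype == "CDS" else "."
            fh.write(
                f"{seqid}\tsweepkit\t{f.ftype}\t{f.start + 1}\t{f.end}\t.\t"
                f"{f.strand}\t{phase}\t{attrs}\n"
            )


def _codon_table(genetic_code: int) -> dict[str, str]:
    table = CodonTable.unambiguous_dna_by_id[genetic_code]
    aa = dict(table.forward_table)
    for stop in table.stop_codons:
        aa[stop] = "*"
    return aa


_SYN_FRACTION_CACHE: dict[int, dict[str, tuple[float, float, float]]] = {}


def codon_syn_fractions(codon: str, genetic_code: int = 1) -> tuple[float, float, float]:
    """NG86 synonymous fraction of each codon position.

    fraction = (# of the 3 possible point mutations at that position that
    preserve the amino acid) / 3. Changes to or from stop codons count as
    nonsynonymous. Stop codons themselves return (0, 0, 0).
    """
    cache = _SYN_FRACTION_CACHE.setdefault(genetic_code, {})
    if codon in cache:
        return cache[codon]
    aa_map = _codon_table(genetic_code)
    aa = aa_map.get(codon)
    if aa is None or aa == "*":
        out = (0.0, 0.0, 0.0)
    else:
        fracs = []
        for pos in range(3):
            syn = 0
            for b in "ACGT":
                if b == codon[pos]:
                    continue
                mut = codon[:pos] + b + codon[pos + 1 :]
                if aa_map.get(mut) == aa:
                    syn += 1
            fracs.append(syn / 3.0)
        out = tuple(fracs)
    cache[codon] = out
    return out


def classify_sites(
    aln: HaplotypeAlignment,
    ann: RegionAnnotation,
    genetic_code: int = 1,
) -> SiteClassification:
    """Assign every alignment column a functional class and NG86 site weight.

    Complete deletion: any column with a gap or N in any sample sequence is
    excluded. Codons containing an excluded column are excluded whole (the
    synonymous fraction of the remaining positions would be ill-defined).
    Coding synonymous fractions are averaged over the sample sequences'
    codons, skipping sequences whose codon contains a stop.
    """
    L = aln.length
    ann.validate(L)
    mat = aln.matrix
    cls = np.full(L, int(SiteClass.EXCLUDED), dtype=int)
    syn = np.full(L, np.nan)
    reasons: dict[int, str] = {}
    codon_map: dict[int, tuple[tuple[int, int, int], int, str, str]] = {}

    has_gap_or_n = np.zeros(L, dtype=bool)
    for c in "N-":
        has_gap_or_n |= (mat == c).any(axis=0)
    covered = np.zeros(L, dtype=bool)

    # non-coding features first; CDS overrides below
    for f in ann.features:
        span = slice(f.start, f.end)
        covered[span] = True
        if f.ftype == "spacer":
            for col in range(f.start, f.end):
                reasons.setdefault(col, "spacer")
        elif f.ftype == "intron":
            cls[span] = int(SiteClass.INTRONIC)
        elif f.ftype in ("intergenic", "flanking"):
            cls[span] = int(SiteClass.INTERGENIC)

    aa_map = _codon_table(genetic_code)
    ref = aln.sequences[0]

    for gene, feats in ann.cds_by_gene().items():
        forward = feats[0].strand == "+"
        feats_sorted = sorted(feats, key=lambda f: f.start, reverse=not forward)
        # transcript-ordered alignment columns where the reference is ungapped
        tcols: list[int] = []
        for f in feats_sorted:
            covered[f.start : f.end] = True
            rng = range(f.start, f.end) if forward else range(f.end - 1, f.start - 1, -1)
            for col in rng:
                if ref[col] == "-":
                    reasons.setdefault(col, "reference-gap")
                else:
                    tcols.append(col)
        offset = feats_sorted[0].phase
        tcols = tcols[offset:]
        if len(tcols) % 3 != 0:
            raise AnnotationError(
                f"CDS of gene {gene!r}: length {len(tcols)} (after gap removal "
                "and phase offset) not divisible by 3"
            )
        n_codons = len(tcols) // 3
        for ci in range(n_codons):
            triple = tuple(tcols[3 * ci : 3 * ci + 3])
            ref_codon = "".join(
                _oriented_base(ref[c], forward) for c in triple
            )
            ref_aa = aa_map.get(ref_codon)
            if ref_aa == "*":
                if ci != n_codons - 1:
                    raise AnnotationError(
                        f"internal stop codon in gene {gene!r} at codon {ci + 1} "
                        f"(alignment columns {[c + 1 for c in triple]})"
                    )
                for col in triple:
                    reasons.setdefault(col, "stop-codon")
                continue
            if any(has_gap_or_n[c] for c in triple):
                for col in triple:
                    reasons.setdefault(
                        col, "gap-or-N" if has_gap_or_n[col] else "codon-incomplete"
                    )
                continue
            # average NG86 fractions over sample sequences
            frac_sum = np.zeros(3)
            n_used = 0
            for row in range(aln.n):
                codon = "".join(
                    _oriented_base(mat[row, c], forward) for c in triple
                )
                if aa_map.get(codon, "*") == "*":
                    continue  # stop in this haplotype; skip in the average
                frac_sum += codon_syn_fractions(codon, genetic_code)
                n_used += 1
            if n_used == 0:
                for col in triple:
                    reasons.setdefault(col, "all-stop-codons")
                continue
            fracs = frac_sum / n_used
            for pos, col in enumerate(triple):
                cls[col] = int(SiteClass.CODING)
                syn[col] = fracs[pos]
                codon_map[col] = (triple, pos, feats_sorted[0].strand, gene)

    # columns not covered by any feature are excluded as unannotated
    for col in np.nonzero(~covered)[0]:
        reasons.setdefault(int(col), "unannotated")
        cls[col] = int(SiteClass.EXCLUDED)
    # complete-deletion on non-coding columns (coding handled per codon)
    noncoding = (cls == SiteClass.INTRONIC) | (cls == SiteClass.INTERGENIC)
    for col in np.nonzero(noncoding & has_gap_or_n)[0]:
        reasons.setdefault(int(col), "gap-or-N")
        cls[col] = int(SiteClass.EXCLUDED)
    # any column assigned a reason is excluded
    for col in reasons:
        cls[col] = int(SiteClass.EXCLUDED)
        syn[col] = np.nan
        codon_map.pop(col, None)

    coding = cls == int(SiteClass.CODING)
    counts = {
        "synonymous": float(np.nansum(syn[coding])),
        "nonsynonymous": float(np.sum(1.0 - syn[coding])),
        "intronic": float(np.sum(cls == int(SiteClass.INTRONIC))),
        "intergenic": float(np.sum(cls == int(SiteClass.INTERGENIC))),
        "coding": float(np.sum(coding)),
        "excluded": float(np.sum(cls == int(SiteClass.EXCLUDED))),
    }
    counts["noncoding"] = counts["intronic"] + counts["intergenic"]
    counts["silent"] = counts["synonymous"] + counts["noncoding"]
    counts["total"] = counts["coding"] + counts["noncoding"]
    return SiteClassification(
        length=L,
        site_class=cls,
        syn_fraction=syn,
        exclusion_reasons=reasons,
        counts=counts,
        codon_map=codon_map,
        genetic_code=genetic_code,
    )


def _oriented_base(b: str, forward: bool) -> str:
    return b if forward else COMPLEMENT.get(b, "N")


@dataclass
class PolymorphismTable:
    """Per-segregating-site table (one region)."""

    region_id: str
    n: int
    length: int
    df: pd.DataFrame  # columns: column, class, alleles, n_alleles, minor_count,
    #                   derived_count, singleton, status

    @property
    def S(self) -> int:
        return len(self.df)

    def polarized(self) -> pd.DataFrame:
        return self.df[self.df["status"] == "polarized"]

    def to_tsv(self, path) -> None:
        out = self.df.copy()
        out.insert(0, "region", self.region_id)
        out.insert(1, "column_1based", out.pop("column") + 1)
        out.to_csv(path, sep="\t", index=False)


def variant_table(
    aln: HaplotypeAlignment,
    classification: Optional[SiteClassification] = None,
    polarize: bool = False,
) -> PolymorphismTable:
    """Tabulate segregating sites; optionally polarize with the outgroup.

    Complete deletion: columns with sample gap/N (or excluded by the
    classification) do not contribute sites. Biallelic sites where the
    outgroup carries one of the two sample alleles are polarized by parsimony;
    outgroup gap/N/third-state and multiallelic sites are retained as
    'unpolarizable' (usable folded, excluded unfolded).
    """
    if polarize and not aln.has_outgroup:
        raise PolarizationError("polarization requested but alignment has no outgroup")
    mat = aln.matrix
    n, L = mat.shape
    if classification is not None:
        included = classification.site_class != int(SiteClass.EXCLUDED)
    else:
        included = ~(np.isin(mat, ["N", "-"]).any(axis=0))
    out = aln.outgroup_array if (polarize and aln.has_outgroup) else None

    rows = []
    for col in np.nonzero(included)[0]:
        col = int(col)
        column = mat[:, col]
        alleles, counts = np.unique(column, return_counts=True)
        if len(alleles) < 2:
            continue
        order = np.argsort(-counts, kind="stable")
        alleles, counts = alleles[order], counts[order]
        allele_str = ",".join(f"{a}:{c}" for a, c in zip(alleles, counts))
        minor = int(counts.min())
        status = "unpolarized"
        derived = pd.NA
        if out is not None:
            if len(alleles) > 2:
                status = "unpolarizable"
            else:
                anc = out[col]
                if anc not in alleles:  # gap, N, or third state
                    status = "unpolarizable"
                else:
                    status = "polarized"
                    derived = int(counts[alleles != anc][0])
        singleton = (derived == 1) if status == "polarized" else (minor == 1)
        cname = (
            classification.class_name(col) if classification is not None else "unclassified"
        )
        is_coding = (
            classification is not None
            and classification.site_class[col] == int(SiteClass.CODING)
        )
        syn_frac = float(classification.syn_fraction[col]) if is_coding else np.nan
        if is_coding:
            w = _change_syn_weight(mat, col, alleles, counts, classification)
            change_type = "synonymous" if w >= 0.5 else "nonsynonymous"
        else:
            w = np.nan
            change_type = "noncoding" if classification is not None else "unclassified"
        rows.append(
            dict(
                column=col,
                **{"class": cname},
                syn_fraction=syn_frac,
                change_syn_weight=w,
                change_type=change_type,
                alleles=allele_str,
                n_alleles=len(alleles),
                minor_count=minor,
                derived_count=derived,
                singleton=bool(singleton),
                status=status,
            )
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "column",
            "class",
            "syn_fraction",
            "change_syn_weight",
            "change_type",
            "alleles",
            "n_alleles",
            "minor_count",
            "derived_count",
            "singleton",
            "status",
        ],
    )
    if len(df):
        df["derived_count"] = df["derived_count"].astype("Int64")
    return PolymorphismTable(region_id=aln.region_id, n=n, length=L, df=df)


def _change_syn_weight(
    mat: np.ndarray,
    col: int,
    alleles: np.ndarray,
    counts: np.ndarray,
    classification: SiteClassification,
) -> float:
    """Synonymous weight of the observed change(s) at a coding column.

    For every unordered allele pair, substitute both alleles into each sample
    sequence's own codon and score 1 if the two codons encode the same amino
    acid (stops score 0); average over sample backgrounds, then over allele
    pairs weighted by their pairwise-comparison counts.
    """
    triple, pos, strand, _ = classification.codon_map[col]
    forward = strand == "+"
    aa_map = _codon_table(classification.genetic_code)
    num = den = 0.0
    for ia in range(len(alleles)):
        for ib in range(ia + 1, len(alleles)):
            a, b = alleles[ia], alleles[ib]
            pair_w = float(counts[ia] * counts[ib])
            syn = 0.0
            for row in range(mat.shape[0]):
                codon = [
                    _oriented_base(mat[row, c], forward) for c in triple
                ]
                ca, cb = codon.copy(), codon.copy()
                ca[pos] = _oriented_base(a, forward)
                cb[pos] = _oriented_base(b, forward)
                aa_a = aa_map.get("".join(ca), "*")
                aa_b = aa_map.get("".join(cb), "*")
                if aa_a == aa_b and aa_a != "*":
                    syn += 1.0
            num += pair_w * syn / mat.shape[0]
            den += pair_w
    return num / den if den else 0.0


def polarize_variants(
    aln: HaplotypeAlignment,
    classification: Optional[SiteClassification] = None,
) -> PolymorphismTable:
    """Outgroup-polarized variant table (requires an outgroup)."""
    return variant_table(aln, classification, polarize=True)
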