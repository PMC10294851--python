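"""Codon-level analyses: CDS extraction, RSCU, and NG86 Ka/Ks.

The genetic code defaults to the invertebrate mitochondrial code (NCBI
translation table 5: AGA/AGG = Ser, ATA = Met, TGA = Trp; stops TAA/TAG).
Mitochondrial protein genes frequently end on a truncated stop codon ("T" or
"TA", completed to TAA by polyadenylation); extraction classifies these as
``T-`` / ``TA-`` from the 1- or 2-bp trailing remainder of the feature span.

Ka/Ks follows the Nei–Gojobori (1986) codon-counting method:

* per-codon synonymous site counts ``s`` are the sum over the three codon
  positions of the synonymous fraction of single-nucleotide changes, with
  changes into stop codons excluded from the denominator; ``n = 3 - s``;
* observed synonymous/nonsynonymous differences between a codon pair
  differing at ``k`` positions are averaged over all ``k!`` mutational
  pathways with equal weight, pathways passing through a stop codon excluded;
* the proportions ``pS = Sd/S`` and ``pN = Nd/N`` are corrected for multiple
  substitutions with the Jukes–Cantor formula
  ``d = -(3/4) ln(1 - (4/3) p)``.

A ratio Ka/Ks > 1 suggests positive selection; < 1, purifying selection.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from functools import lru_cache
from itertools import permutations

from Bio.Data import CodonTable

from .annotation_io import MitogenomeRecord, ValidationError

__all__ = [
    "GeneticCode",
    "INVERTEBRATE_MITO",
    "CdsExtract",
    "CodonUsageTable",
    "KaKsResult",
    "extract_cds",
    "rscu",
    "pcg_codon_counts",
    "ng86_site_counts",
    "ng86_pairwise",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class GeneticCode:
    """Codon -> amino-acid map plus stop set for one translation table."""

    table_id: int
    forward: dict  # codon -> one-letter amino acid, sense codons only
    stops: frozenset

    @classmethod
    def from_table_id(cls, table_id: int) -> "GeneticCode":
        table = CodonTable.unambiguous_dna_by_id[table_id]
        return cls(table_id=table_id,
                   forward=dict(table.forward_table),
                   stops=frozenset(table.stop_codons))

    @property
    def sense_codons(self) -> list[str]:
        return sorted(self.forward)

    def translate(self, codon: str) -> str:
        codon = codon.upper()
        if codon in self.stops:
            return "*"
        return self.forward[codon]

    def is_stop(self, codon: str) -> bool:
        return codon.upper() in self.stops


#: NCBI translation table 5, the default throughout the package.
INVERTEBRATE_MITO = GeneticCode.from_table_id(5)


# ---------------------------------------------------------------------------
# CDS extraction
# ---------------------------------------------------------------------------

_REVCOMP = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_REVCOMP)[::-1]


@dataclass(frozen=True)
class CdsExtract:
    """An in-frame protein-coding sequence in coding-strand orientation."""

    gene: str
    codons: tuple[str, ...]
    start_codon: str
    stop_class: str  # TAA | TAG | T- | TA-
    trailing_len: int  # 0, 1 or 2 bp of incomplete terminal codon
    internal_stops: tuple[int, ...] = ()  # 0-based codon indices, if any


def stop_class_from_trailing(trailing_len: int, final_codon: str | None = None) -> str:
    """Stop classification from the out-of-frame remainder of a feature span."""
    if trailing_len == 1:
        return "T-"
    if trailing_len == 2:
        return "TA-"
    return final_codon or "TAA"


def extract_cds(record: MitogenomeRecord, gene: str,
                code: GeneticCode = INVERTEBRATE_MITO) -> CdsExtract:
    """Extract the in-frame codons of a protein-coding feature.

    Minus-strand features are reverse complemented before framing.  A 1- or
    2-bp remainder after the last full codon is an incomplete stop ("T-" /
    "TA-"); with no remainder the final triplet must be a stop codon.
    Internal stop codons are reported with a warning, not an error.
    """
    feat = record.feature(gene)
    if feat.type != "PCG":
        raise ValidationError(f"{gene} is not a protein-coding gene")
    if feat.size < 6:
        raise ValidationError(f"{gene}: feature too short ({feat.size} bp) for a CDS")
    seq = record.feature_sequence(gene, oriented=True)
    trailing = len(seq) % 3
    codons = tuple(seq[i:i + 3] for i in range(0, len(seq) - trailing, 3))
    internal = tuple(i for i, c in enumerate(codons[:-1]) if code.is_stop(c))
    if trailing == 0 and not code.is_stop(codons[-1]):
        warnings.warn(f"{record.id}/{gene}: final codon {codons[-1]} is not a "
                      "stop codon", stacklevel=2)
    if internal:
        warnings.warn(f"{record.id}/{gene}: internal stop codon(s) at codon "
                      f"index {list(internal)}", stacklevel=2)
    return CdsExtract(
        gene=gene, codons=codons, start_codon=codons[0],
        stop_class=stop_class_from_trailing(trailing, codons[-1]),
        trailing_len=trailing, internal_stops=internal,
    )


# ---------------------------------------------------------------------------
# RSCU
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CodonUsageTable:
    """Per-codon counts and relative synonymous codon usage.

    RSCU(c) = count(c) * family_size / total family count: the observed count
    relative to uniform usage within the codon's synonymous family.  Families
    with zero total usage carry RSCU 0 for all members and are listed in
    ``empty_families``.
    """

    rows: tuple[tuple[str, str, int, float], ...]  # (codon, aa, count, rscu)
    empty_families: tuple[str, ...]

    def as_dict(self) -> dict[str, float]:
        return {codon: r for codon, _aa, _n, r in self.rows}

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame(self.rows, columns=["codon", "aa", "count", "RSCU"])


def rscu(codon_counts: dict[str, int],
         code: GeneticCode = INVERTEBRATE_MITO) -> CodonUsageTable:
    """Relative synonymous codon usage over sense-codon counts.

    Stop codons are excluded from synonymous families (and must not appear in
    the counts).
    """
    for codon in codon_counts:
        if code.is_stop(codon):
            raise ValidationError(f"stop codon {codon} in RSCU counts")
    families: dict[str, list[str]] = {}
    for codon in code.sense_codons:
        families.setdefault(code.forward[codon], []).append(codon)
    rows = []
    empty = []
    for aa in sorted(families):
        members = families[aa]
        total = sum(codon_counts.get(c, 0) for c in members)
        if total == 0:
            empty.append(aa)
        for c in members:
            value = 0.0 if total == 0 else codon_counts.get(c, 0) * len(members) / total
            rows.append((c, aa, codon_counts.get(c, 0), value))
    return CodonUsageTable(rows=tuple(rows), empty_families=tuple(empty))


def pcg_codon_counts(record: MitogenomeRecord,
                     code: GeneticCode = INVERTEBRATE_MITO) -> dict[str, int]:
    """Codon counts over all 13 PCGs concatenated, for whole-proteome RSCU.

    Start codons are included; terminal stop codons and incomplete terminal
    codons are excluded.
    """
    counts: dict[str, int] = {}
    for feat in record.features_of_type("PCG"):
        cds = extract_cds(record, feat.name, code)
        codons = cds.codons
        if cds.trailing_len == 0 and code.is_stop(codons[-1]):
            codons = codons[:-1]
        for c in codons:
            if not code.is_stop(c):  # internal stops excluded from usage
                counts[c] = counts.get(c, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# NG86 Ka/Ks
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _site_counts_cached(codon: str, table_id: int) -> tuple[float, float]:
    code = GeneticCode.from_table_id(table_id)
    aa = code.forward[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        valid = 0
        for base in _BASES:
            if base == codon[pos]:
                continue
            neighbor = codon[:pos] + base + codon[pos + 1:]
            if code.is_stop(neighbor):
                continue  # stop neighbors excluded from the denominator
            valid += 1
            if code.forward[neighbor] == aa:
                syn += 1
        if valid:
            s += syn / valid
    return s, 3.0 - s


def ng86_site_counts(codon: str,
                     code: GeneticCode = INVERTEBRATE_MITO) -> tuple[float, float]:
    """Synonymous/nonsynonymous site counts (s, n) of one sense codon.

    ``s`` sums, over the three positions, the fraction of single-nucleotide
    changes that are synonymous, with changes into stop codons excluded from
    the denominator; ``n = 3 - s``.
    """
    codon = codon.upper()
    if code.is_stop(codon):
        raise ValidationError(f"stop codon {codon} has no site counts")
    if codon not in code.forward:
        raise ValidationError(f"not a sense codon: {codon!r}")
    return _site_counts_cached(codon, code.table_id)


def _pathway_differences(codon_a: str, codon_b: str,
                         code: GeneticCode) -> tuple[float, float]:
    """(syn, nonsyn) differences averaged over all equal-weight mutational
    pathways between two sense codons; pathways through stops excluded."""
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0
    totals = []
    for order in permutations(diff_pos):
        cur = codon_a
        syn = nonsyn = 0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1:]
            if code.is_stop(nxt):
                blocked = True
                break
            if code.forward[cur] == code.forward[nxt]:
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        if not blocked:
            totals.append((syn, nonsyn))
    if not totals:
        # every pathway crosses a stop codon; fall back to counting along
        # all pathways regardless (rare, keeps the estimator defined)
        for order in permutations(diff_pos):
            cur = codon_a
            syn = nonsyn = 0
            for pos in order:
                nxt = cur[:pos] + codon_b[pos] + cur[pos + 1:]
                if code.is_stop(nxt) or code.is_stop(cur):
                    nonsyn += 1
                elif code.forward[cur] == code.forward[nxt]:
                    syn += 1
                else:
                    nonsyn += 1
                cur = nxt
            totals.append((syn, nonsyn))
    sd = sum(t[0] for t in totals) / len(totals)
    nd = sum(t[1] for t in totals) / len(totals)
    return sd, nd


def _jukes_cantor(p: float) -> float:
    """Multiple-substitution correction d = -(3/4) ln(1 - (4/3) p)."""
    if p >= 0.75:
        return math.nan
    if p == 0.0:
        return 0.0
    return -0.75 * math.log1p(-4.0 * p / 3.0)


@dataclass(frozen=True)
class KaKsResult:
    """Site counts, difference counts and corrected NG86 distances.

    ``ratio`` is NaN when Ks is 0 or either corrected distance is undefined
    (observed proportion beyond the Jukes–Cantor saturation bound of 3/4).
    """

    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    Ks: float
    Ka: float
    ratio: float
    codons_compared: int

    @property
    def saturated(self) -> bool:
        return math.isnan(self.Ks) or math.isnan(self.Ka)


_SKIP_CHARS = set("-N?")


def _usable(codon_a: str, codon_b: str, code: GeneticCode) -> bool:
    if len(codon_a) != 3 or len(codon_b) != 3:
        return False
    if _SKIP_CHARS & (set(codon_a) | set(codon_b)):
        return False
    return (codon_a in code.forward or code.is_stop(codon_a)) and \
           (codon_b in code.forward or code.is_stop(codon_b))


def ng86_pairwise(codons_a, codons_b,
                  code: GeneticCode = INVERTEBRATE_MITO) -> KaKsResult:
    """NG86 Ka/Ks between two aligned, in-frame codon sequences.

    Codon pairs containing gaps, ambiguous bases, incomplete terminal codons
    or stop codons (in either sequence) are dropped pairwise.  Site counts
    are averaged over the two sequences; differences are averaged over all
    mutational pathways per codon pair.
    """
    codons_a = [c.upper() for c in codons_a]
    codons_b = [c.upper() for c in codons_b]
    if len(codons_a) != len(codons_b):
        raise ValidationError(
            f"codon sequences differ in length ({len(codons_a)} vs "
            f"{len(codons_b)}); align per gene first")
    S = N = Sd = Nd = 0.0
    used = 0
    for ca, cb in zip(codons_a, codons_b):
        if not _usable(ca, cb, code) or code.is_stop(ca) or code.is_stop(cb):
            continue
        used += 1
        sa, na = ng86_site_counts(ca, code)
        sb, nb = ng86_site_counts(cb, code)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        sd, nd = _pathway_differences(ca, cb, code)
        Sd += sd
        Nd += nd
    if used == 0:
        raise ValidationError("no comparable codon pairs")
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    Ks = _jukes_cantor(pS)
    Ka = _jukes_cantor(pN)
    if math.isnan(Ks) or math.isnan(Ka) or Ks == 0.0:
        ratio = math.nan
    else:
        ratio = Ka / Ks
    return KaKsResult(S=S, N=N, Sd=Sd, Nd=Nd, pS=pS, pN=pN,
                      Ks=Ks, Ka=Ka, ratio=ratio, codons_compared=used)


def kaks_table(query: MitogenomeRecord, reference: MitogenomeRecord,
               genes: list[str] | None = None,
               code: GeneticCode = INVERTEBRATE_MITO):
    """Per-gene NG86 results between two records with attached sequences.

    Genes are compared codon-by-codon and must have equal coding length in
    the two records (inputs are assumed pre-aligned per gene); genes failing
    that precondition are skipped with a warning.
    """
    import pandas as pd
    names = genes or [f.name for f in query.features_of_type("PCG")]
    rows = []
    for name in names:
        try:
            a = extract_cds(query, name, code)
            b = extract_cds(reference, name, code)
            if len(a.codons) != len(b.codons):
                warnings.warn(f"{name}: coding lengths differ "
                              f"({len(a.codons)} vs {len(b.codons)} codons); "
                              "skipped", stacklevel=2)
                continue
            r = ng86_pairwise(a.codons, b.codons, code)
        except (ValidationError, KeyError) as exc:
            warnings.warn(f"{name}: {exc}", stacklevel=2)
            continue
        rows.append({"gene": name, "S": r.S, "N": r.N, "Sd": r.Sd, "Nd": r.Nd,
                     "Ks": r.Ks, "Ka": r.Ka, "Ka/Ks": r.ratio,
                     "codons": r.codons_compared})
    return pd.DataFrame(rows)
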