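"""Seeded generation of synthetic circular mitogenomes and perturbed data.

The generator emulates the gross architecture of an insect mitogenome — the
37-gene vocabulary plus control region laid out on a circle, AT-biased base
composition, protein genes with valid start codons (ATN, rarely TTG), no
internal stops and complete (TAA/TAG) or incomplete (T-/TA-) stop codons,
tRNAs of 55–74 bp — while making no attempt at realistic sequence homology,
secondary structure, or substitution processes along a phylogeny.  Its
purpose is to give every pipeline stage a statistically controlled,
download-free input with a known ground truth.

All randomness flows through one :class:`numpy.random.Generator` seeded from
``SimulationConfig.seed``: fixed seed, byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annotation_io import CR, GeneFeature, MitogenomeRecord, ValidationError
from .codon_evolution import INVERTEBRATE_MITO, GeneticCode
from .gene_order import (ANCESTRAL_INSECT_ORDER, GeneOrder, RearrangementEvent,
                         apply_event)

__all__ = [
    "SimulationConfig",
    "simulate_genome",
    "apply_rearrangement",
    "random_event",
    "mutate_coding_pair",
]

_TYPE_BY_PREFIX = {"trn": "tRNA", "rrn": "rRNA"}

#: Default per-gene coding lengths (complete codons, start included), spanning
#: the observed range in pteromalid mitogenomes: atp8 shortest, nad5 longest.
PCG_CODON_RANGES: dict[str, tuple[int, int]] = {
    "atp8": (53, 55), "atp6": (225, 226), "cox1": (510, 512),
    "cox2": (223, 226), "cox3": (262, 263), "cytb": (379, 383),
    "nad1": (307, 312), "nad2": (334, 338), "nad3": (116, 118),
    "nad4": (444, 448), "nad4l": (96, 97), "nad5": (556, 563),
    "nad6": (182, 190),
}


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions for one synthetic mitogenome.

    Lengths are in bp except ``pcg_codons`` (complete codons).  ``at`` is the
    target A+T fraction of the whole molecule (the pteromalid average is
    ~0.84); the control region may carry its own AT target.  The gene-order
    template defaults to the putative ancestral insect arrangement.
    """

    template: GeneOrder = ANCESTRAL_INSECT_ORDER
    at: float = 0.84
    cr_at: float | None = None
    trna_len: tuple[int, int] = (55, 74)
    rrns_len: tuple[int, int] = (763, 787)
    rrnl_len: tuple[int, int] = (1300, 1325)
    cr_len: tuple[int, int] = (183, 390)
    pcg_codons: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(PCG_CODON_RANGES))
    spacer_len: tuple[int, int] = (0, 20)
    p_incomplete_stop: float = 0.25
    p_ttg_start: float = 0.02
    p_tag_stop: float = 0.1
    code: GeneticCode = INVERTEBRATE_MITO
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.at <= 1.0:
            raise ValidationError("AT target must lie in [0, 1]")
        for lo, hi in (self.trna_len, self.rrns_len, self.rrnl_len,
                       self.cr_len, self.spacer_len):
            if lo < 0 or hi < lo:
                raise ValidationError(f"invalid length range ({lo}, {hi})")
        for gene, (lo, hi) in self.pcg_codons.items():
            if lo < 2 or hi < lo:
                raise ValidationError(f"{gene}: invalid codon range ({lo}, {hi})")


def _base_probs(at: float) -> np.ndarray:
    return np.array([at / 2, at / 2, (1 - at) / 2, (1 - at) / 2])


_ALPHABET = np.array(list("ATGC"))


def _draw_bases(rng: np.random.Generator, k: int, at: float) -> str:
    if k == 0:
        return ""
    return "".join(rng.choice(_ALPHABET, size=k, p=_base_probs(at)))


_REVCOMP = str.maketrans("ACGT", "TGCA")


def _simulate_cds(rng: np.random.Generator, gene: str,
                  cfg: SimulationConfig) -> tuple[str, str, str]:
    """Return (cds sequence incl. any trailing bases, start_codon, stop_class)."""
    lo, hi = cfg.pcg_codons.get(gene, (100, 500))
    n_codons = int(rng.integers(lo, hi + 1))
    has_gc = cfg.at < 1.0  # G-bearing codons only when composition admits G
    if rng.random() < cfg.p_ttg_start and has_gc:
        start = "TTG"
    else:
        start = "AT" + _draw_bases(rng, 1, cfg.at)
    incomplete = rng.random() < cfg.p_incomplete_stop
    n_internal = n_codons - 1 if incomplete else n_codons - 2
    internals = []
    while len(internals) < n_internal:
        codon = _draw_bases(rng, 3, cfg.at)
        if not cfg.code.is_stop(codon):  # resample internal stop codons
            internals.append(codon)
    if incomplete:
        trailing = "T" if rng.random() < 0.5 else "TA"
        stop_class = trailing + "-"
        tail = trailing
    else:
        tail = "TAG" if (rng.random() < cfg.p_tag_stop and has_gc) else "TAA"
        stop_class = tail
    return start + "".join(internals) + tail, start, stop_class


def simulate_genome(config: SimulationConfig | None = None) -> MitogenomeRecord:
    """Simulate one annotated circular mitogenome with sequence.

    Genes follow the template order and strands; minus-strand genes are
    generated in coding orientation and reverse complemented into the
    molecule.  Genes are separated by short non-coding spacers (no overlaps),
    so bp conservation holds exactly: genome length = feature spans plus
    intergenic spans.
    """
    cfg = config or SimulationConfig()
    rng = np.random.default_rng(cfg.seed)
    chunks: list[str] = []
    features: list[GeneFeature] = []
    pos = 1
    for name, sign in cfg.template.genes:
        start_codon = stop_codon = None
        if name == CR:
            ftype = "control_region"
            seq = _draw_bases(rng, int(rng.integers(*cfg.cr_len, endpoint=True)),
                              cfg.at if cfg.cr_at is None else cfg.cr_at)
        elif name.startswith("trn"):
            ftype = "tRNA"
            seq = _draw_bases(rng, int(rng.integers(*cfg.trna_len, endpoint=True)),
                              cfg.at)
        elif name.startswith("rrn"):
            ftype = "rRNA"
            rng_len = cfg.rrns_len if name == "rrnS" else cfg.rrnl_len
            seq = _draw_bases(rng, int(rng.integers(*rng_len, endpoint=True)),
                              cfg.at)
        else:
            ftype = "PCG"
            seq, start_codon, stop_codon = _simulate_cds(rng, name, cfg)
        if sign == "-":
            genome_seq = seq.translate(_REVCOMP)[::-1]
        else:
            genome_seq = seq
        end = pos + len(genome_seq) - 1
        features.append(GeneFeature(name, pos, end, sign, ftype,
                                    start_codon, stop_codon))
        chunks.append(genome_seq)
        spacer = _draw_bases(rng, int(rng.integers(*cfg.spacer_len, endpoint=True)),
                             cfg.at)
        chunks.append(spacer)
        pos = end + len(spacer) + 1
    sequence = "".join(chunks)
    return MitogenomeRecord(id=f"sim_seed{cfg.seed}", length=len(sequence),
                            features=features, sequence=sequence)


def apply_rearrangement(order: GeneOrder, event: RearrangementEvent,
                        seed: int | None = None) -> GeneOrder:
    """Apply one rearrangement event; the seed drives TDRL random loss."""
    rng = np.random.default_rng(seed) if seed is not None else None
    return apply_event(order, event, rng=rng)


def random_event(order: GeneOrder, kind: str, rng: np.random.Generator,
                 max_segment: int = 6) -> RearrangementEvent:
    """Draw a random valid, non-identity event of the requested kind."""
    n = len(order.genes)
    if n < max_segment + 3:
        raise ValidationError("order too short for the requested segment size")
    length = int(rng.integers(1, max_segment + 1))
    start = int(rng.integers(n))
    idx = [(start + k) % n for k in range(length)]
    segment = tuple(order.genes[j][0] for j in idx)
    if kind == "inversion":
        return RearrangementEvent(kind="inversion", segment=segment)
    if kind in ("transposition", "reverse_transposition"):
        predecessor = order.genes[(start - 1) % n][0]
        candidates = [g for g, _ in order.genes
                      if g not in segment and g != predecessor]
        after = candidates[int(rng.integers(len(candidates)))]
        return RearrangementEvent(kind=kind, segment=segment, after=after)
    if kind == "tdrl_or_complex":
        return RearrangementEvent(kind="tdrl_or_complex", segment=segment)
    raise ValidationError(f"unknown event kind {kind!r}")


def mutate_coding_pair(codons, n_syn: int, n_nonsyn: int,
                       code: GeneticCode = INVERTEBRATE_MITO,
                       seed: int | None = None) -> list[str]:
    """Plant exact numbers of synonymous/nonsynonymous point changes.

    Each change replaces one codon (all at distinct codon positions) with a
    single-nucleotide neighbour that is not a stop codon — synonymous
    (same amino acid) or nonsynonymous as requested.  Raises when the
    sequence cannot host the requested changes.
    """
    rng = np.random.default_rng(seed)
    codons = [c.upper() for c in codons]

    def neighbours(codon: str, synonymous: bool) -> list[str]:
        out = []
        for pos in range(3):
            for base in "ACGT":
                if base == codon[pos]:
                    continue
                cand = codon[:pos] + base + codon[pos + 1:]
                if code.is_stop(cand):
                    continue
                if (code.forward[cand] == code.forward[codon]) == synonymous:
                    out.append(cand)
        return out

    result = list(codons)
    available = [i for i, c in enumerate(codons)
                 if len(c) == 3 and not code.is_stop(c) and c in code.forward]
    rng.shuffle(available)
    for synonymous, wanted in ((True, n_syn), (False, n_nonsyn)):
        placed = 0
        remaining = []
        for i in available:
            if placed == wanted:
                remaining.append(i)
                continue
            options = neighbours(codons[i], synonymous)
            if options:
                result[i] = options[int(rng.integers(len(options)))]
                placed += 1
            else:
                remaining.append(i)
        if placed < wanted:
            raise ValidationError(
                f"cannot place {wanted} {'synonymous' if synonymous else 'nonsynonymous'} "
                f"changes; only {placed} codons qualify")
        available = remaining
    return result
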