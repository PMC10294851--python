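"""Reading, validating and writing annotated mitogenome records.

The module owns the canonical 37-gene vocabulary of the insect mitochondrial
genome (13 protein-coding genes, 22 tRNAs, 2 rRNAs) plus the AT-rich control
region (symbol ``CR``), and two on-disk representations:

* a plain tab-separated *gene table* (one feature per row, 1-based fully
  inclusive coordinates) — the format every other module consumes, and
* GenBank flat files, parsed through Biopython with product/gene names mapped
  onto the canonical vocabulary.

Coordinates are 1-based and inclusive on both ends, so a tRNA annotated
``1..69`` has size 69.  Records describe circular molecules: the junction
between the last listed feature and the first is a real adjacency.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

__all__ = [
    "PCGS",
    "TRNAS",
    "RRNAS",
    "CR",
    "GENE_VOCABULARY",
    "GeneFeature",
    "MitogenomeRecord",
    "ValidationError",
    "parse_gene_table",
    "write_gene_table",
    "parse_genbank",
    "write_genbank",
    "read_fasta_sequence",
    "write_fasta",
]

PCGS = (
    "atp6", "atp8", "cox1", "cox2", "cox3", "cytb",
    "nad1", "nad2", "nad3", "nad4", "nad4l", "nad5", "nad6",
)
TRNAS = (
    "trnA", "trnC", "trnD", "trnE", "trnF", "trnG", "trnH", "trnI", "trnK",
    "trnL1", "trnL2", "trnM", "trnN", "trnP", "trnQ", "trnR", "trnS1",
    "trnS2", "trnT", "trnV", "trnW", "trnY",
)
RRNAS = ("rrnS", "rrnL")
CR = "CR"
GENE_VOCABULARY = frozenset(PCGS) | frozenset(TRNAS) | frozenset(RRNAS) | {CR}

_TYPE_BY_GENE = (
    {g: "PCG" for g in PCGS}
    | {g: "tRNA" for g in TRNAS}
    | {g: "rRNA" for g in RRNAS}
    | {CR: "control_region"}
)

FEATURE_TYPES = ("PCG", "tRNA", "rRNA", "control_region")

#: Incomplete stop codons completed to TAA by post-transcriptional
#: polyadenylation; "T" / "TA" in annotation tables are normalized to these.
VALID_STOPS = ("TAA", "TAG", "T-", "TA-")

GENE_TABLE_COLUMNS = ("gene", "start", "end", "strand", "type",
                      "start_codon", "stop_codon")


class ValidationError(ValueError):
    """A record or table violates the coordinate/vocabulary contract."""


# ---------------------------------------------------------------------------
# Name mapping: free-text GenBank labels -> canonical symbols
# ---------------------------------------------------------------------------

#: Anticodon-based disambiguation of the duplicated leucine and serine tRNAs,
#: following the universal mitochondrial convention (the codon family each
#: isoacceptor reads): L(UUR)=trnL2 anticodon TAA, L(CUN)=trnL1 anticodon TAG,
#: S(UCN)=trnS2 anticodon TGA, S(AGN)=trnS1 anticodon GCT.
ANTICODON_TO_TRNA = {
    ("L", "TAA"): "trnL2",
    ("L", "TAG"): "trnL1",
    ("S", "TGA"): "trnS2",
    ("S", "GCT"): "trnS1",
}

_NAME_ALIASES = {
    # protein-coding genes
    "nd1": "nad1", "nd2": "nad2", "nd3": "nad3", "nd4": "nad4",
    "nd4l": "nad4l", "nd5": "nad5", "nd6": "nad6",
    "nadh1": "nad1", "nadh2": "nad2", "nadh3": "nad3", "nadh4": "nad4",
    "nadh4l": "nad4l", "nadh5": "nad5", "nadh6": "nad6",
    "co1": "cox1", "co2": "cox2", "co3": "cox3",
    "coi": "cox1", "coii": "cox2", "coiii": "cox3",
    "cox1": "cox1", "cox2": "cox2", "cox3": "cox3",
    "coxi": "cox1", "coxii": "cox2", "coxiii": "cox3",
    "cob": "cytb", "cytb": "cytb", "cytochrome b": "cytb",
    "atp6": "atp6", "atp8": "atp8", "atpase6": "atp6", "atpase8": "atp8",
    # rRNAs
    "rrnl": "rrnL", "rrns": "rrnS",
    "16s": "rrnL", "12s": "rrnS",
    "16s ribosomal rna": "rrnL", "12s ribosomal rna": "rrnS",
    "l-rrna": "rrnL", "s-rrna": "rrnS",
    "large subunit ribosomal rna": "rrnL",
    "small subunit ribosomal rna": "rrnS",
    # control region
    "cr": CR, "at-rich": CR, "at-rich region": CR, "a+t-rich region": CR,
    "d-loop": CR, "control region": CR, "putative control region": CR,
}

_AA3_TO_1 = {
    "ala": "A", "arg": "R", "asn": "N", "asp": "D", "cys": "C", "gln": "Q",
    "glu": "E", "gly": "G", "his": "H", "ile": "I", "leu": "L", "lys": "K",
    "met": "M", "phe": "F", "pro": "P", "ser": "S", "thr": "T", "trp": "W",
    "tyr": "Y", "val": "V",
}


def _canonical_gene_name(raw: str, anticodon: str | None = None) -> str | None:
    """Map a free-text feature label onto the canonical vocabulary.

    Returns None when the label cannot be mapped.  Leucine/serine tRNAs are
    disambiguated by the supplied anticodon, or by an anticodon embedded in
    the label itself, e.g. ``trnL(taa)``.
    """
    label = raw.strip()
    if not label:
        return None
    key = label.lower()
    if key in _NAME_ALIASES:
        return _NAME_ALIASES[key]

    # exact canonical symbols (case-insensitive on the trn prefix letter case)
    for sym in GENE_VOCABULARY:
        if key == sym.lower():
            return sym

    # tRNA spellings: trnX, trnX(nnn), tRNA-Xxx, tRNA-Xxx (nnn)
    embedded_ac = None
    if "(" in key and key.endswith(")"):
        key, _, ac = key.partition("(")
        embedded_ac = ac.rstrip(")").strip().upper().replace("U", "T")
        key = key.strip()
    ac = (anticodon or embedded_ac or "").upper().replace("U", "T") or None

    aa = None
    if key.startswith("trna-") or key.startswith("trna "):
        tail = key[5:].strip()
        aa = _AA3_TO_1.get(tail[:3]) if len(tail) >= 3 else None
        if aa is None and len(tail) == 1:
            aa = tail.upper()
        if aa is None and tail[:3] not in _AA3_TO_1 and len(tail) >= 1:
            aa = tail[0].upper() if tail[0].upper() in "ACDEFGHIKLMNPQRSTVWY" else None
    elif key.startswith("trn") and len(key) >= 4:
        aa = key[3].upper()
        if len(key) >= 5 and key[4] in "12":
            cand = f"trn{aa}{key[4]}"
            return cand if cand in GENE_VOCABULARY else None
    if aa is not None:
        if aa in ("L", "S"):
            if ac and (aa, ac) in ANTICODON_TO_TRNA:
                return ANTICODON_TO_TRNA[(aa, ac)]
            return None  # ambiguous without an anticodon
        cand = f"trn{aa}"
        return cand if cand in GENE_VOCABULARY else None
    return None


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneFeature:
    """One annotated feature, 1-based inclusive coordinates on the molecule."""

    name: str
    start: int
    end: int
    strand: str
    type: str
    start_codon: str | None = None
    stop_codon: str | None = None

    def __post_init__(self) -> None:
        if self.name not in GENE_VOCABULARY:
            raise ValidationError(f"unknown gene symbol: {self.name!r}")
        if self.start < 1:
            raise ValidationError(f"{self.name}: start must be >= 1")
        if self.end < self.start:
            raise ValidationError(
                f"{self.name}: end ({self.end}) < start ({self.start})")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"{self.name}: strand must be + or -")
        if self.type not in FEATURE_TYPES:
            raise ValidationError(f"{self.name}: unknown feature type {self.type!r}")
        expected = _TYPE_BY_GENE[self.name]
        if self.type != expected:
            raise ValidationError(
                f"{self.name}: type {self.type!r} inconsistent with symbol "
                f"(expected {expected!r})")
        if self.stop_codon is not None and self.stop_codon not in VALID_STOPS:
            raise ValidationError(
                f"{self.name}: stop codon {self.stop_codon!r} not in {VALID_STOPS}")

    @property
    def size(self) -> int:
        return self.end - self.start + 1


@dataclass
class MitogenomeRecord:
    """An annotated circular mitogenome: features plus optional sequence."""

    id: str
    length: int
    features: list[GeneFeature]
    circular: bool = True
    sequence: str | None = None
    skipped_features: list[str] = field(default_factory=list, compare=False)

    def __post_init__(self) -> None:
        self.features = sorted(self.features, key=lambda f: (f.start, f.end))
        seen: set[str] = set()
        for f in self.features:
            if f.name in seen:
                raise ValidationError(f"duplicate gene name: {f.name}")
            seen.add(f.name)
            if f.end > self.length:
                raise ValidationError(
                    f"{f.name}: end {f.end} exceeds genome length {self.length}")
        if sum(1 for f in self.features if f.type == "control_region") > 1:
            raise ValidationError("more than one control region feature")
        if self.sequence is not None:
            self.sequence = self.sequence.upper()
            if len(self.sequence) != self.length:
                raise ValidationError(
                    f"sequence length {len(self.sequence)} != declared length "
                    f"{self.length}")
            bad = set(self.sequence) - set("ACGTN")
            if bad:
                raise ValidationError(f"sequence contains invalid characters {bad}")

    def feature(self, name: str) -> GeneFeature:
        for f in self.features:
            if f.name == name:
                return f
        raise KeyError(name)

    def features_of_type(self, ftype: str) -> list[GeneFeature]:
        return [f for f in self.features if f.type == ftype]

    @property
    def is_complete(self) -> bool:
        """True when the record carries all 37 genes plus the control region."""
        names = {f.name for f in self.features}
        return names >= (GENE_VOCABULARY - {CR}) and CR in names

    def feature_sequence(self, name: str, oriented: bool = True) -> str:
        """Sub-sequence of a feature; reverse-complemented for minus strand
        when ``oriented`` is true."""
        if self.sequence is None:
            raise ValidationError(f"record {self.id} has no sequence attached")
        f = self.feature(name)
        seq = self.sequence[f.start - 1:f.end]
        if oriented and f.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq


# ---------------------------------------------------------------------------
# Gene-table TSV
# ---------------------------------------------------------------------------

def parse_gene_table(text: str) -> MitogenomeRecord:
    """Parse a tab-separated gene table into a validated record.

    The format carries record metadata in leading ``#`` comment lines
    (``# id=...``, ``# length=...``, ``# circular=true``) followed by a header
    row ``gene	start	end	strand	type	start_codon	stop_codon``.  Empty
    codon fields mean "not applicable".  The strand column accepts the ASCII
    hyphen and the typographic minus sign.
    """
    meta: dict[str, str] = {}
    rows: list[list[str]] = []
    header: list[str] | None = None
    for raw_line in text.splitlines():
        line = raw_line.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                k, _, v = body.partition("=")
                meta[k.strip()] = v.strip()
            continue
        cells = line.split("\t")
        if header is None:
            header = [c.strip() for c in cells]
            missing = set(GENE_TABLE_COLUMNS[:5]) - set(header)
            if missing:
                raise ValidationError(f"gene table header missing columns {missing}")
            continue
        rows.append(cells)
    if header is None or not rows:
        raise ValidationError("empty gene table")

    idx = {name: header.index(name) for name in header}

    def cell(row: list[str], col: str) -> str:
        i = idx.get(col)
        if i is None or i >= len(row):
            return ""
        return row[i].strip()

    features = []
    for row in rows:
        name = cell(row, "gene").replace("−", "-")
        name = {"AT-rich": CR}.get(name, name)
        if name not in GENE_VOCABULARY:
            mapped = _canonical_gene_name(name)
            if mapped is None:
                raise ValidationError(f"unknown gene symbol: {name!r}")
            name = mapped
        strand = cell(row, "strand").replace("−", "-") or "+"
        ftype = cell(row, "type") or _TYPE_BY_GENE[name]
        start_codon = cell(row, "start_codon") or None
        stop_codon = cell(row, "stop_codon") or None
        if stop_codon in ("T", "TA"):  # incomplete stops as printed in tables
            stop_codon += "-"
        try:
            start, end = int(cell(row, "start")), int(cell(row, "end"))
        except ValueError as exc:
            raise ValidationError(f"{name}: non-integer coordinates") from exc
        features.append(GeneFeature(name, start, end, strand, ftype,
                                    start_codon, stop_codon))

    length = int(meta.get("length", max(f.end for f in features)))
    circular = meta.get("circular", "true").lower() != "false"
    return MitogenomeRecord(id=meta.get("id", "unnamed"), length=length,
                            circular=circular, features=features)


def write_gene_table(record: MitogenomeRecord) -> str:
    """Serialize a record to the normalized gene-table TSV.

    Deterministic column order and formatting; ``parse_gene_table`` of the
    output reproduces the record exactly (sequence excluded).
    """
    lines = [
        f"# id={record.id}",
        f"# length={record.length}",
        f"# circular={'true' if record.circular else 'false'}",
        "\t".join(GENE_TABLE_COLUMNS),
    ]
    for f in record.features:
        lines.append("\t".join([
            f.name, str(f.start), str(f.end), f.strand, f.type,
            f.start_codon or "", f.stop_codon or "",
        ]))
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# GenBank / FASTA
# ---------------------------------------------------------------------------

_GB_FEATURE_TYPES = ("CDS", "tRNA", "rRNA", "D-loop", "misc_feature", "gene")


def parse_genbank(source) -> MitogenomeRecord:
    """Parse a GenBank flat file into a canonical record.

    ``source`` is a path or an open text handle.  Features whose labels
    cannot be mapped onto the canonical vocabulary are skipped with a warning
    and listed in ``record.skipped_features``.  Records without an ORIGIN
    block load without sequence.
    """
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    seqrec = SeqIO.read(source, "genbank")
    try:
        sequence = str(seqrec.seq).upper()
        if not sequence or set(sequence) <= {"N"} and len(sequence) == 0:
            sequence = None
    except Exception:  # Bio raises UndefinedSequenceError without ORIGIN
        sequence = None
    length = len(seqrec) if sequence is None else len(sequence)

    features: dict[str, GeneFeature] = {}
    skipped: list[str] = []
    for feat in seqrec.features:
        if feat.type not in _GB_FEATURE_TYPES or feat.type == "gene":
            continue
        quals = feat.qualifiers
        labels = quals.get("gene", []) + quals.get("product", []) + quals.get("note", [])
        anticodon = None
        for ac in quals.get("anticodon", []):
            # e.g. "(pos:...,aa:Leu,seq:taa)"
            if "seq:" in ac:
                anticodon = ac.split("seq:")[1].strip(") ").upper().replace("U", "T")
        if feat.type == "D-loop":
            labels = labels or ["D-loop"]
        name = None
        for label in labels:
            name = _canonical_gene_name(label, anticodon=anticodon)
            if name is not None:
                break
        if name is None:
            label = labels[0] if labels else feat.type
            warnings.warn(f"skipping unmappable feature {label!r}", stacklevel=2)
            skipped.append(label)
            continue
        if name in features:
            continue  # keep first occurrence (gene + CDS pairs)
        start = int(feat.location.start) + 1  # Biopython is 0-based half-open
        end = int(feat.location.end)
        strand = "-" if feat.location.strand == -1 else "+"
        features[name] = GeneFeature(name, start, end, strand, _TYPE_BY_GENE[name])

    return MitogenomeRecord(id=seqrec.id or seqrec.name, length=length,
                            features=list(features.values()),
                            sequence=sequence, skipped_features=skipped)


_GB_PRODUCTS = {
    "atp6": "ATP synthase F0 subunit 6", "atp8": "ATP synthase F0 subunit 8",
    "cox1": "cytochrome c oxidase subunit I",
    "cox2": "cytochrome c oxidase subunit II",
    "cox3": "cytochrome c oxidase subunit III",
    "cytb": "cytochrome b",
    "nad1": "NADH dehydrogenase subunit 1", "nad2": "NADH dehydrogenase subunit 2",
    "nad3": "NADH dehydrogenase subunit 3", "nad4": "NADH dehydrogenase subunit 4",
    "nad4l": "NADH dehydrogenase subunit 4L",
    "nad5": "NADH dehydrogenase subunit 5", "nad6": "NADH dehydrogenase subunit 6",
    "rrnL": "16S ribosomal RNA", "rrnS": "12S ribosomal RNA",
}

_TRNA_ANTICODON = {v: k for k, v in ANTICODON_TO_TRNA.items()}


def write_genbank(record: MitogenomeRecord, handle) -> None:
    """Write a record with attached sequence as a GenBank flat file."""
    if record.sequence is None:
        raise ValidationError("GenBank output requires an attached sequence")
    seqrec = SeqRecord(Seq(record.sequence), id=record.id, name=record.id[:16],
                       description="mitochondrion, complete genome")
    seqrec.annotations["molecule_type"] = "DNA"
    seqrec.annotations["topology"] = "circular" if record.circular else "linear"
    for f in record.features:
        loc = FeatureLocation(f.start - 1, f.end, strand=-1 if f.strand == "-" else 1)
        if f.type == "PCG":
            quals = {"gene": [f.name], "product": [_GB_PRODUCTS[f.name]]}
            seqrec.features.append(SeqFeature(loc, type="CDS", qualifiers=quals))
        elif f.type == "rRNA":
            quals = {"gene": [f.name], "product": [_GB_PRODUCTS[f.name]]}
            seqrec.features.append(SeqFeature(loc, type="rRNA", qualifiers=quals))
        elif f.type == "tRNA":
            quals = {"gene": [f.name]}
            if f.name in _TRNA_ANTICODON:
                aa, ac = _TRNA_ANTICODON[f.name]
                quals["note"] = [f"{f.name}({ac.lower()})"]
            seqrec.features.append(SeqFeature(loc, type="tRNA", qualifiers=quals))
        else:
            seqrec.features.append(SeqFeature(loc, type="D-loop",
                                              qualifiers={"note": ["A+T-rich region"]}))
    SeqIO.write(seqrec, handle, "genbank")


def read_fasta_sequence(source, record_id: str | None = None) -> str:
    """Load one sequence from a FASTA file (by id when given, else the first)."""
    for rec in SeqIO.parse(source, "fasta"):
        if record_id is None or rec.id == record_id:
            return str(rec.seq).upper()
    raise ValidationError(f"no FASTA record {record_id!r} found")


def attach_sequence(record: MitogenomeRecord, sequence: str) -> MitogenomeRecord:
    """Return a copy of the record with the sequence attached and validated."""
    return MitogenomeRecord(id=record.id, length=record.length,
                            features=list(record.features),
                            circular=record.circular, sequence=sequence,
                            skipped_features=list(record.skipped_features))


def write_fasta(record: MitogenomeRecord, handle) -> None:
    if record.sequence is None:
        raise ValidationError("record has no sequence to write")
    seqrec = SeqRecord(Seq(record.sequence), id=record.id, description="")
    SeqIO.write(seqrec, handle, "fasta")
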