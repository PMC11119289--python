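"""Readers and writers for the external formats the pipeline touches.

Coordinates are GFF3-style (1-based, inclusive) everywhere inside the
package; the BED convention (0-based, half-open) appears only at the BED
write boundary.  The domain-hit table is a deliberately small TSV dialect
(header ``gene_id<TAB>accessions[<TAB>evalue<TAB>coverage]``, accessions
';'-separated) matching the shape of dbCAN/Pfam overview exports.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

from gffutils.feature import feature_from_line

logger = logging.getLogger(__name__)


class GffParseError(ValueError):
    """Malformed GFF3 input; the message names the offending line."""


class TsvFormatError(ValueError):
    """Domain/PUL TSV whose header or fields violate the dialect."""


# ---------------------------------------------------------------------------
# core records


@dataclass(frozen=True)
class GeneRecord:
    """One annotated gene (or CDS): 1-based inclusive span on a contig."""

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str
    product: str | None = None

    def __post_init__(self) -> None:
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"gene {self.gene_id}: need 1 <= start <= end, "
                f"got {self.start}..{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class DomainHit:
    """One domain/CAZyme-family assignment for a gene."""

    gene_id: str
    source: str
    accession: str
    evalue: float | None = None
    coverage: float | None = None

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("accession must be non-empty")
        if self.evalue is not None and self.evalue < 0:
            raise ValueError(f"{self.gene_id}/{self.accession}: evalue < 0")
        if self.coverage is not None and not (0.0 <= self.coverage <= 1.0):
            raise ValueError(f"{self.gene_id}/{self.accession}: coverage outside [0,1]")


@dataclass
class AnnotationBundle:
    """Sorted gene models plus their domain hits."""

    genes: list[GeneRecord]
    hits: list[DomainHit] = field(default_factory=list)
    provenance: str = ""

    def __post_init__(self) -> None:
        self.genes = sorted(self.genes, key=lambda g: (g.contig, g.start, g.end))
        ids = [g.gene_id for g in self.genes]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate gene_id(s): {dup[:5]}")
        known = set(ids)
        for h in self.hits:
            if h.gene_id not in known:
                raise ValueError(f"domain hit for unknown gene {h.gene_id!r}")

    def hits_by_gene(self) -> dict[str, list[DomainHit]]:
        out: dict[str, list[DomainHit]] = {g.gene_id: [] for g in self.genes}
        for h in self.hits:
            out[h.gene_id].append(h)
        return out


# ---------------------------------------------------------------------------
# GFF3


def parse_gff(
    path: str | Path,
    feature_types: Sequence[str] | None = None,
) -> AnnotationBundle:
    """Read gene models from a GFF3 file.

    By default CDS features are used, falling back to ``gene`` features
    when the file contains no CDS.  Identity is taken from the first of
    the ``ID``, ``locus_tag``, ``Name`` attributes.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    by_type: dict[str, list[GeneRecord]] = {}
    wanted = tuple(feature_types) if feature_types else ("CDS", "gene")
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if stripped == "##FASTA":
                break
            if not stripped or stripped.startswith("#"):
                continue
            if stripped.count("\t") < 7:
                raise GffParseError(f"{path.name} line {lineno}: not a 9-column GFF3 line")
            try:
                feat = feature_from_line(line)
            except Exception as exc:
                raise GffParseError(f"{path.name} line {lineno}: {exc}") from exc
            if feat.featuretype not in wanted:
                continue
            gene_id = None
            for key in ("ID", "locus_tag", "Name"):
                if key in feat.attributes and feat.attributes[key]:
                    gene_id = feat.attributes[key][0]
                    break
            if gene_id is None:
                raise GffParseError(
                    f"{path.name} line {lineno}: feature "
                    f"{feat.seqid}:{feat.start}-{feat.end} has no ID/locus_tag/Name"
                )
            if feat.end < feat.start:
                raise GffParseError(
                    f"{path.name} line {lineno}: end < start for {gene_id}"
                )
            if feat.strand not in ("+", "-"):
                raise GffParseError(
                    f"{path.name} line {lineno}: feature {gene_id} has no strand"
                )
            product = feat.attributes["product"][0] if "product" in feat.attributes else None
            by_type.setdefault(feat.featuretype, []).append(
                GeneRecord(gene_id, feat.seqid, feat.start, feat.end, feat.strand, product)
            )
    if feature_types:
        genes = [g for t in wanted for g in by_type.get(t, [])]
    else:
        genes = by_type.get("CDS") or by_type.get("gene") or []
    return AnnotationBundle(genes=genes, provenance=f"parse_gff:{path.name}")


def write_gff(bundle: AnnotationBundle, path: str | Path, feature_type: str = "CDS") -> None:
    """Write gene models back out as minimal GFF3."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##gff-version 3\n")
        for g in bundle.genes:
            attrs = f"ID={g.gene_id}"
            if g.product:
                attrs += f";product={g.product}"
            fh.write(
                f"{g.contig}\tpulfinder\t{feature_type}\t{g.start}\t{g.end}"
                f"\t.\t{g.strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# domain-hit TSV

_DOMAIN_HEADERS = (
    ["gene_id", "accessions"],
    ["gene_id", "accessions", "evalue"],
    ["gene_id", "accessions", "evalue", "coverage"],
)


def parse_domain_tsv(path: str | Path, source: str) -> list[DomainHit]:
    """Read the ';'-separated domain/CAZyme assignment table."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    hits: list[DomainHit] = []
    with path.open() as fh:
        header: list[str] | None = None
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if header is None:
                if fields not in [list(h) for h in _DOMAIN_HEADERS]:
                    raise TsvFormatError(
                        f"{path.name}: unknown header {fields!r}; expected "
                        "gene_id<TAB>accessions[<TAB>evalue[<TAB>coverage]]"
                    )
                header = fields
                continue
            if len(fields) < 2:
                raise TsvFormatError(f"{path.name} line {lineno}: fewer than 2 fields")
            gene_id = fields[0].strip()
            try:
                evalue = coverage = None
                if len(header) >= 3 and len(fields) >= 3 and fields[2].strip():
                    evalue = float(fields[2])
                if len(header) >= 4 and len(fields) >= 4 and fields[3].strip():
                    coverage = float(fields[3])
                for token in fields[1].split(";"):
                    acc = token.strip()
                    if not acc:
                        logger.warning(
                            "%s line %d: empty accession token for %s skipped",
                            path.name, lineno, gene_id,
                        )
                        continue
                    hits.append(DomainHit(gene_id, source, acc, evalue, coverage))
            except ValueError as exc:
                raise TsvFormatError(f"{path.name} line {lineno}: {exc}") from exc
    if header is None:
        raise TsvFormatError(f"{path.name}: empty file (no header)")
    return hits


def write_domain_tsv(hits: Iterable[DomainHit], path: str | Path) -> None:
    """Write hits grouped per gene in the same dialect parse_domain_tsv reads."""
    grouped: dict[str, list[DomainHit]] = {}
    order: list[str] = []
    for h in hits:
        if h.gene_id not in grouped:
            order.append(h.gene_id)
        grouped.setdefault(h.gene_id, []).append(h)
    with Path(path).open("w") as fh:
        fh.write("gene_id\taccessions\tevalue\tcoverage\n")
        for gid in order:
            accs = ";".join(h.accession for h in grouped[gid])
            ev = grouped[gid][0].evalue
            cov = grouped[gid][0].coverage
            fh.write(
                f"{gid}\t{accs}\t{'' if ev is None else ev}\t"
                f"{'' if cov is None else cov}\n"
            )


# ---------------------------------------------------------------------------
# PUL table / BED

PUL_TABLE_COLUMNS = [
    "pul_id", "contig", "start", "end", "n_genes", "n_pairs",
    "strand_consensus", "cazyme_families", "regulators", "substrate_calls",
    "gene_ids", "n_sulfatases",
]


@dataclass(frozen=True)
class PulTableRow:
    """One deserialized row of the PUL table (enough to re-score substrates)."""

    pul_id: str
    contig: str
    start: int
    end: int
    n_genes: int
    n_pairs: int
    strand_consensus: str
    cazyme_families: tuple[str, ...]
    regulators: tuple[str, ...]
    substrate_calls: tuple[tuple[str, float], ...]
    gene_ids: tuple[str, ...]
    n_sulfatases: int


def write_pul_table(puls: Iterable, path: str | Path) -> None:
    """Serialize called PULs as TSV (one row per locus)."""
    with Path(path).open("w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(PUL_TABLE_COLUMNS)
        for p in puls:
            calls = ";".join(f"{c.substrate}:{c.score:.1f}" for c in p.substrate_calls)
            w.writerow([
                p.pul_id, p.contig, p.start, p.end,
                len(p.member_gene_ids), len(p.pair_blocks),
                p.strand_consensus,
                ";".join(sorted(p.cazyme_families)),
                ";".join(p.regulators),
                calls,
                ";".join(p.member_gene_ids),
                p.n_sulfatases,
            ])


def read_pul_table(path: str | Path) -> list[PulTableRow]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    rows: list[PulTableRow] = []
    with path.open() as fh:
        r = csv.reader(fh, delimiter="\t")
        header = next(r, None)
        if header != PUL_TABLE_COLUMNS:
            raise TsvFormatError(f"{path.name}: unexpected PUL table header {header!r}")
        for fields in r:
            if not fields:
                continue
            d = dict(zip(PUL_TABLE_COLUMNS, fields))
            calls = []
            for tok in d["substrate_calls"].split(";"):
                if tok:
                    name, _, score = tok.rpartition(":")
                    calls.append((name, float(score)))
            rows.append(PulTableRow(
                pul_id=d["pul_id"], contig=d["contig"],
                start=int(d["start"]), end=int(d["end"]),
                n_genes=int(d["n_genes"]), n_pairs=int(d["n_pairs"]),
                strand_consensus=d["strand_consensus"],
                cazyme_families=tuple(t for t in d["cazyme_families"].split(";") if t),
                regulators=tuple(t for t in d["regulators"].split(";") if t),
                substrate_calls=tuple(calls),
                gene_ids=tuple(t for t in d["gene_ids"].split(";") if t),
                n_sulfatases=int(d["n_sulfatases"]),
            ))
    return rows


def write_pul_bed(puls: Iterable, path: str | Path) -> None:
    """BED6: 0-based half-open spans; score column carries the pair count."""
    with Path(path).open("w") as fh:
        for p in puls:
            fh.write(
                f"{p.contig}\t{p.start - 1}\t{p.end}\t{p.pul_id}"
                f"\t{len(p.pair_blocks)}\t{p.strand_consensus}\n"
            )


# ---------------------------------------------------------------------------
# sequence utility


class SkewWindow(NamedTuple):
    start: int        # 1-based window start
    skew: float
    zero_gc: bool     # window contained no G or C; skew reported as 0.0


def gc_skew(sequence: str, window: int, step: int) -> list[SkewWindow]:
    """Sliding-window GC skew, (G − C)/(G + C), over full windows only.

    Windows without any G or C yield skew 0.0 with ``zero_gc`` set, so
    downstream summaries stay numeric.
    """
    if not sequence:
        raise ValueError("empty sequence")
    if window < 1 or step < 1:
        raise ValueError("window and step must be >= 1")
    bad = set(sequence.upper()) - set("ACGTN")
    if bad:
        raise ValueError(f"sequence contains non-ACGTN symbols: {sorted(bad)}")
    seq = sequence.upper()
    out: list[SkewWindow] = []
    for off in range(0, len(seq) - window + 1, step):
        chunk = seq[off:off + window]
        g = chunk.count("G")
        c = chunk.count("C")
        if g + c == 0:
            out.append(SkewWindow(off + 1, 0.0, True))
        else:
            out.append(SkewWindow(off + 1, (g - c) / (g + c), False))
    return out
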