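"""Tandem SusC/SusD locus calling.

The locus model: a polysaccharide utilization locus (PUL) is anchored by a
tandem pair block — one or more adjacent SusC-like genes immediately
followed, in transcription order on the same strand, by one or more
SusD-like genes ("duplications" of either partner collapse into the same
block).  From each anchor the locus is extended outward over neighbouring
CAZyme, sulfatase, regulator and further SusC/SusD genes, tolerating short
runs of unannotated genes, until the gap rule (too many unknown genes in a
row, or too large an intergenic distance) stops it.  Overlapping extensions
merge into a single locus.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from enum import Enum

from .annotation_io import AnnotationBundle, GeneRecord
from .config import GapConfig, RoleConfig, RunConfig, default_config

logger = logging.getLogger(__name__)

#: CAZy family label: class prefix + family number, optional subfamily.
CAZY_FAMILY_RE = re.compile(r"(GH|GT|PL|CE|AA|CBM)\d+(?:_\d+)?$")


class Role(str, Enum):
    SUSC = "SUSC"
    SUSD = "SUSD"
    CAZYME = "CAZYME"
    REGULATOR = "REGULATOR"
    SULFATASE = "SULFATASE"
    UNKNOWN = "UNKNOWN"


class RegulatorKind(str, Enum):
    HTCS = "HTCS"
    ECF_SIGMA = "ECF_SIGMA"
    ANTI_SIGMA = "ANTI_SIGMA"
    NONE = "NONE"


#: conflict resolution: transporter signatures anchor the locus, so they win.
ROLE_PRIORITY = [Role.SUSC, Role.SUSD, Role.CAZYME, Role.SULFATASE, Role.REGULATOR]

#: roles the outward walk may absorb into a locus.
ABSORBABLE = {Role.SUSC, Role.SUSD, Role.CAZYME, Role.SULFATASE, Role.REGULATOR}


@dataclass(frozen=True)
class RoleAssignment:
    gene_id: str
    role: Role
    families: tuple[str, ...] = ()
    regulator_kind: RegulatorKind = RegulatorKind.NONE

    def __post_init__(self) -> None:
        if (self.role == Role.CAZYME) != bool(self.families):
            raise ValueError(
                f"{self.gene_id}: families must be non-empty iff role=CAZYME"
            )
        if (self.role == Role.REGULATOR) != (self.regulator_kind != RegulatorKind.NONE):
            raise ValueError(
                f"{self.gene_id}: regulator_kind set iff role=REGULATOR"
            )


@dataclass(frozen=True)
class TandemPairBlock:
    """Anchor of a PUL: SusC gene(s) then SusD gene(s) on one strand."""

    susc_gene_ids: tuple[str, ...]
    susd_gene_ids: tuple[str, ...]
    strand: str
    contig: str
    start: int
    end: int


@dataclass
class PUL:
    pul_id: str
    contig: str
    member_gene_ids: list[str]
    pair_blocks: list[TandemPairBlock]
    cazyme_families: list[str]          # multiset, sorted
    regulators: list[str]               # regulator kinds in coordinate order
    start: int
    end: int
    strand_consensus: str               # '+', '-' or '.' when blocks disagree
    n_sulfatases: int = 0
    substrate_calls: list = field(default_factory=list)

    @property
    def cazyme_free(self) -> bool:
        return not self.cazyme_families


# ---------------------------------------------------------------------------
# role assignment


def _role_candidates(accessions: set[str], rc: RoleConfig) -> list[RoleAssignment]:
    """All roles the accession set supports, before priority resolution."""
    cands: list[tuple[Role, tuple[str, ...], RegulatorKind]] = []
    if rc.susc_require and rc.susc_require <= accessions:
        cands.append((Role.SUSC, (), RegulatorKind.NONE))
    if accessions & rc.susd_any:
        cands.append((Role.SUSD, (), RegulatorKind.NONE))
    families = sorted({a for a in accessions if CAZY_FAMILY_RE.match(a)})
    if families:
        cands.append((Role.CAZYME, tuple(families), RegulatorKind.NONE))
    if accessions & rc.sulfatase_any:
        cands.append((Role.SULFATASE, (), RegulatorKind.NONE))
    if rc.htcs_require <= accessions:
        kind = RegulatorKind.HTCS
    elif rc.ecf_sigma_require <= accessions:
        kind = RegulatorKind.ECF_SIGMA
    elif accessions & rc.anti_sigma_any:
        kind = RegulatorKind.ANTI_SIGMA
    else:
        kind = RegulatorKind.NONE
    if kind != RegulatorKind.NONE:
        cands.append((Role.REGULATOR, (), kind))
    return [RoleAssignment("_", r, f, k) for r, f, k in cands]


def assign_roles(
    bundle: AnnotationBundle,
    role_config: RoleConfig | None = None,
) -> list[RoleAssignment]:
    """One RoleAssignment per gene, conflicts resolved by fixed priority."""
    rc = role_config or default_config().roles
    by_gene = bundle.hits_by_gene()
    out: list[RoleAssignment] = []
    for gene in bundle.genes:
        accs = {h.accession for h in by_gene[gene.gene_id]}
        cands = _role_candidates(accs, rc)
        if not cands:
            out.append(RoleAssignment(gene.gene_id, Role.UNKNOWN))
            continue
        if len(cands) > 1:
            roles = sorted(c.role.value for c in cands)
            logger.warning(
                "gene %s matches several roles %s; keeping highest priority",
                gene.gene_id, roles,
            )
        best = min(cands, key=lambda c: ROLE_PRIORITY.index(c.role))
        out.append(RoleAssignment(
            gene.gene_id, best.role, best.families, best.regulator_kind
        ))
    return out


def _roles_by_id(roles: list[RoleAssignment]) -> dict[str, RoleAssignment]:
    return {r.gene_id: r for r in roles}


# ---------------------------------------------------------------------------
# tandem pair detection


def find_tandem_pairs(
    genes: list[GeneRecord],
    roles: list[RoleAssignment],
    gap_config: GapConfig | None = None,
) -> list[TandemPairBlock]:
    """Maximal SusC-run → SusD-run blocks, per contig and strand.

    In transcription order (the default) "upstream" on the minus strand
    means higher coordinates, so a minus-strand block reads SusD…SusC in
    plus-coordinate order.  ``pair_orientation = plus_coordinate`` instead
    requires SusC…SusD in plus-coordinate order on both strands.
    """
    gc = gap_config or default_config().gaps
    role_of = _roles_by_id(roles)
    blocks: list[TandemPairBlock] = []
    by_contig: dict[str, list[GeneRecord]] = {}
    for g in sorted(genes, key=lambda g: (g.contig, g.start, g.end)):
        by_contig.setdefault(g.contig, []).append(g)

    for contig, cgenes in by_contig.items():
        n = len(cgenes)
        i = 0
        while i < n:
            g = cgenes[i]
            role = role_of[g.gene_id].role
            strand = g.strand
            if gc.pair_orientation == "plus_coordinate" or strand == "+":
                first, second = Role.SUSC, Role.SUSD
            else:
                first, second = Role.SUSD, Role.SUSC  # minus strand, coord order
            if role != first:
                i += 1
                continue
            # maximal run of the leading partner
            j = i
            while j + 1 < n and cgenes[j + 1].strand == strand \
                    and role_of[cgenes[j + 1].gene_id].role == first:
                j += 1
            # optional relaxed gap of non-SusC/SusD genes between the runs
            k = j + 1
            gap_used = 0
            while (k < n and gap_used < gc.pair_max_gap_genes
                   and role_of[cgenes[k].gene_id].role not in (Role.SUSC, Role.SUSD)):
                k += 1
                gap_used += 1
            # maximal run of the trailing partner
            m = k
            while m < n and cgenes[m].strand == strand \
                    and role_of[cgenes[m].gene_id].role == second:
                m += 1
            if m == k:  # no trailing partner: no block here
                i = j + 1
                continue
            members = cgenes[i:j + 1] + cgenes[k:m]
            first_ids = tuple(g.gene_id for g in cgenes[i:j + 1])
            second_ids = tuple(g.gene_id for g in cgenes[k:m])
            if first == Role.SUSC:
                susc_ids, susd_ids = first_ids, second_ids
            else:
                # minus strand in coordinate order: SusD run came first
                susc_ids, susd_ids = second_ids, first_ids
            blocks.append(TandemPairBlock(
                susc_gene_ids=susc_ids,
                susd_gene_ids=susd_ids,
                strand=strand,
                contig=contig,
                start=min(g.start for g in members),
                end=max(g.end for g in members),
            ))
            i = m
    return blocks


# ---------------------------------------------------------------------------
# locus extension


def _extend_window(
    cgenes: list[GeneRecord],
    role_of: dict[str, RoleAssignment],
    left: int,
    right: int,
    gc: GapConfig,
) -> tuple[int, int]:
    """Greedy outward walk from gene indices [left, right]; returns final span."""
    # leftward
    i = left - 1
    pending = 0
    while i >= 0:
        gap_bp = cgenes[i + 1].start - cgenes[i].end - 1
        if gap_bp > gc.max_gap_bp:
            break
        if role_of[cgenes[i].gene_id].role in ABSORBABLE:
            left = i
            pending = 0
        else:
            pending += 1
            if pending > gc.max_gap_genes:
                break
        i -= 1
    # rightward
    i = right + 1
    pending = 0
    n = len(cgenes)
    while i < n:
        gap_bp = cgenes[i].start - cgenes[i - 1].end - 1
        if gap_bp > gc.max_gap_bp:
            break
        if role_of[cgenes[i].gene_id].role in ABSORBABLE:
            right = i
            pending = 0
        else:
            pending += 1
            if pending > gc.max_gap_genes:
                break
        i += 1
    return left, right


def _make_pul(
    pul_id: str,
    contig: str,
    members: list[GeneRecord],
    blocks: list[TandemPairBlock],
    role_of: dict[str, RoleAssignment],
) -> PUL:
    families: list[str] = []
    regulators: list[str] = []
    n_sulf = 0
    for g in members:
        r = role_of[g.gene_id]
        if r.role == Role.CAZYME:
            families.extend(r.families)
        elif r.role == Role.REGULATOR:
            regulators.append(r.regulator_kind.value)
        elif r.role == Role.SULFATASE:
            n_sulf += 1
    strands = {b.strand for b in blocks}
    return PUL(
        pul_id=pul_id,
        contig=contig,
        member_gene_ids=[g.gene_id for g in members],
        pair_blocks=sorted(blocks, key=lambda b: b.start),
        cazyme_families=sorted(families),
        regulators=regulators,
        start=min(g.start for g in members),
        end=max(g.end for g in members),
        strand_consensus=strands.pop() if len(strands) == 1 else ".",
        n_sulfatases=n_sulf,
    )


def extend_to_pul(
    block: TandemPairBlock,
    genes: list[GeneRecord],
    roles: list[RoleAssignment],
    gap_config: GapConfig | None = None,
) -> PUL:
    """Extend a single pair block to its full locus (unnumbered id)."""
    gc = gap_config or default_config().gaps
    role_of = _roles_by_id(roles)
    cgenes = sorted(
        (g for g in genes if g.contig == block.contig),
        key=lambda g: (g.start, g.end),
    )
    idx = {g.gene_id: i for i, g in enumerate(cgenes)}
    member_idx = [idx[i] for i in block.susc_gene_ids + block.susd_gene_ids]
    left, right = _extend_window(cgenes, role_of, min(member_idx), max(member_idx), gc)
    return _make_pul("PUL?", block.contig, cgenes[left:right + 1], [block], role_of)


# ---------------------------------------------------------------------------
# whole-genome prediction


def predict_puls(
    bundle: AnnotationBundle,
    config: RunConfig | None = None,
) -> list[PUL]:
    """Assign roles, find pair blocks, extend, merge overlaps, number.

    Returns loci sorted by (contig, start), numbered PUL1, PUL2, … in that
    order.  Loci whose extended spans overlap are merged (union of member
    genes, pair blocks concatenated).
    """
    cfg = config or default_config()
    roles = assign_roles(bundle, cfg.roles)
    role_of = _roles_by_id(roles)
    blocks = find_tandem_pairs(bundle.genes, roles, cfg.gaps)

    by_contig: dict[str, list[GeneRecord]] = {}
    for g in bundle.genes:
        by_contig.setdefault(g.contig, []).append(g)

    raw: list[tuple[str, int, int, TandemPairBlock]] = []
    for b in blocks:
        cgenes = by_contig[b.contig]
        idx = {g.gene_id: i for i, g in enumerate(cgenes)}
        member_idx = [idx[i] for i in b.susc_gene_ids + b.susd_gene_ids]
        left, right = _extend_window(
            cgenes, role_of, min(member_idx), max(member_idx), cfg.gaps
        )
        raw.append((b.contig, left, right, b))

    # merge windows with overlapping gene-index ranges per contig
    merged: list[tuple[str, int, int, list[TandemPairBlock]]] = []
    for contig in sorted({r[0] for r in raw}):
        windows = sorted((r for r in raw if r[0] == contig), key=lambda r: (r[1], r[2]))
        cur: tuple[int, int, list[TandemPairBlock]] | None = None
        for _, lo, hi, blk in windows:
            if cur is not None and lo <= cur[1]:
                cur = (cur[0], max(cur[1], hi), cur[2] + [blk])
            else:
                if cur is not None:
                    merged.append((contig, *cur))
                cur = (lo, hi, [blk])
        if cur is not None:
            merged.append((contig, *cur))

    merged.sort(key=lambda m: (m[0], by_contig[m[0]][m[1]].start))
    puls: list[PUL] = []
    for ordinal, (contig, lo, hi, blks) in enumerate(merged, start=1):
        members = by_contig[contig][lo:hi + 1]
        puls.append(_make_pul(f"PUL{ordinal}", contig, members, blks, role_of))
    return puls
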