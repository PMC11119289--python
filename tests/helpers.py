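"""Shared builders for compact in-memory genome fixtures.

A genome is written as a list of role tokens, one per gene in coordinate
order: 'C' (SusC-like), 'D' (SusD-like), 'U' (unknown), 'SULF', 'HTCS',
'ECF', 'ANTI', or any CAZy family label like 'GH16'.  Strands default to
'+' and can be given per gene.
"""

from __future__ import annotations

from pulfinder.annotation_io import AnnotationBundle, DomainHit, GeneRecord
from pulfinder.config import default_config

_CFG = default_config()

TOKEN_ACCESSIONS = {
    "C": sorted(_CFG.roles.susc_require),
    "D": [sorted(_CFG.roles.susd_any)[0]],
    "SULF": [sorted(_CFG.roles.sulfatase_any)[0]],
    "HTCS": sorted(_CFG.roles.htcs_require),
    "ECF": sorted(_CFG.roles.ecf_sigma_require),
    "ANTI": [sorted(_CFG.roles.anti_sigma_any)[0]],
    "U": [],
}

TOKEN_ROLE = {
    "C": "SUSC", "D": "SUSD", "SULF": "SULFATASE",
    "HTCS": "REGULATOR", "ECF": "REGULATOR", "ANTI": "REGULATOR",
    "U": "UNKNOWN",
}


def token_accessions(token: str) -> list[str]:
    if token in TOKEN_ACCESSIONS:
        return TOKEN_ACCESSIONS[token]
    return [token]  # CAZy family label


def token_role(token: str) -> str:
    return TOKEN_ROLE.get(token, "CAZYME")


def build_bundle(
    tokens: list[str],
    strands: list[str] | None = None,
    gaps: list[int] | int = 100,
    gene_len: int = 900,
    contig: str = "c1",
    start: int = 1000,
) -> AnnotationBundle:
    """Genes laid left to right with the given intergenic gaps."""
    n = len(tokens)
    strands = strands or ["+"] * n
    if isinstance(gaps, int):
        gaps = [gaps] * n
    genes, hits = [], []
    pos = start
    for i, (tok, strand) in enumerate(zip(tokens, strands)):
        gid = f"{contig}_g{i + 1:03d}"
        genes.append(GeneRecord(gid, contig, pos, pos + gene_len - 1, strand))
        for acc in token_accessions(tok):
            hits.append(DomainHit(gid, "fixture", acc))
        pos += gene_len + gaps[i]
    return AnnotationBundle(genes=genes, hits=hits)


def roles_of(tokens: list[str]) -> list[str]:
    """Ground-truth role names for a token list, independent of assign_roles."""
    return [token_role(t) for t in tokens]
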