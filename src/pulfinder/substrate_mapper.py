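"""Score PULs against CAZyme-family signatures of four marine polysaccharides.

Each substrate has a core family set (weight 1.0 per distinct matched
family) and an accessory set (weight 0.5), e.g. sulfatase co-occurrence as
accessory evidence for the sulfated fucoidan.  Family multiplicity within a
locus never raises the score; only distinct matched families count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .config import RunConfig, default_config

#: pseudo-family label matched by sulfatase-role genes in a locus
SULFATASE_LABEL = "SULFATASE"


@dataclass(frozen=True)
class SubstrateSignature:
    substrate: str
    core_families: frozenset[str]
    accessory_families: frozenset[str] = frozenset()
    core_weight: float = 1.0
    accessory_weight: float = 0.5

    def __post_init__(self) -> None:
        if not self.core_families:
            raise ValueError(f"{self.substrate}: core families must be non-empty")
        if self.core_families & self.accessory_families:
            raise ValueError(f"{self.substrate}: core and accessory overlap")


@dataclass(frozen=True)
class SubstrateCall:
    pul_id: str
    substrate: str
    score: float
    evidence: tuple[tuple[str, str], ...]  # (family, "core" | "accessory")


def default_signatures() -> list[SubstrateSignature]:
    """The four study polysaccharides with their shipped family sets."""
    return signatures_from_config(default_config())


def signatures_from_config(config: RunConfig) -> list[SubstrateSignature]:
    return [
        SubstrateSignature(name, core, accessory)
        for name, (core, accessory) in sorted(config.substrates.items())
    ]


def _evidence_families(pul) -> set[str]:
    fams = set(pul.cazyme_families)
    if getattr(pul, "n_sulfatases", 0) > 0:
        fams.add(SULFATASE_LABEL)
    return fams


def map_substrates(
    pul,
    signatures: Iterable[SubstrateSignature] | None = None,
) -> list[SubstrateCall]:
    """Ranked substrate calls for one PUL (score desc, then substrate name).

    Accepts any object carrying ``pul_id``, ``cazyme_families`` and
    ``n_sulfatases`` — a freshly predicted :class:`~pulfinder.pul_predictor.PUL`
    or a deserialized PUL-table row.  PULs matching nothing yield an empty
    list; zero-score calls are never emitted.
    """
    sigs = list(signatures) if signatures is not None else default_signatures()
    present = _evidence_families(pul)
    calls: list[SubstrateCall] = []
    for sig in sigs:
        core = sorted(present & sig.core_families)
        accessory = sorted(present & sig.accessory_families)
        score = sig.core_weight * len(core) + sig.accessory_weight * len(accessory)
        if score > 0:
            evidence = tuple([(f, "core") for f in core]
                            + [(f, "accessory") for f in accessory])
            calls.append(SubstrateCall(pul.pul_id, sig.substrate, score, evidence))
    calls.sort(key=lambda c: (-c.score, c.substrate))
    return calls
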