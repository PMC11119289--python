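"""Synthetic annotated genomes with planted PULs, plus fermentation series.

The genome generator plants loci with the structural grammar of marine-
polysaccharide PULs — an optional regulator (HTCS or ECF-sigma), flanking
CAZymes drawn from the planted substrate's family signature, and a tandem
SusC/SusD pair with optional duplication of either partner — into a
background of unannotated genes, together with decoy arrangements (lone
SusC, lone SusD, wrong-order pairs, strand-split pairs, scattered CAZymes)
that exercise every exclusion branch of the pair-detection rule.  Domain
hits are emitted consistent with the default role map, so re-deriving
roles from the hits reproduces the planted roles exactly.

The fermentation generator emulates batch-culture trajectories: logistic
OD600 growth, exponentially declining residual total sugar, and
exponentially declining molecular weight, sampled on the study's time grid
with multiplicative Gaussian noise and triplicates.

All randomness flows from a single seeded generator per call; identical
seeds give byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .annotation_io import (
    AnnotationBundle,
    DomainHit,
    GeneRecord,
    write_domain_tsv,
    write_gff,
)
from .config import RunConfig, default_config
from .fermentation_analysis import DEFAULT_TIMES_H, TimeSeries, write_timeseries_csv


class CapacityError(ValueError):
    """Requested loci/decoys do not fit in the contig gene budget."""


@dataclass(frozen=True)
class DecoyRates:
    """Per-gene-budget rates of each decoy arrangement (fractions in [0,1])."""

    lone_susc: float = 0.0
    lone_susd: float = 0.0
    wrong_order_pair: float = 0.0
    opposite_strand_pair: float = 0.0
    scattered_cazyme: float = 0.0

    def __post_init__(self) -> None:
        for name in ("lone_susc", "lone_susd", "wrong_order_pair",
                     "opposite_strand_pair", "scattered_cazyme"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"decoy rate {name} outside [0,1]")


@dataclass(frozen=True)
class GenomeSimSpec:
    n_contigs: int = 1
    genes_per_contig: int = 400
    n_puls: int = 10
    pul_cazyme_range: tuple[int, int] = (1, 4)
    p_duplicated_pair: float = 0.3
    p_regulator: float = 0.7
    decoy_rates: DecoyRates = field(default_factory=DecoyRates)
    mean_gene_len: int = 1200
    mean_intergenic: int = 150
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_contigs < 1 or self.genes_per_contig < 1 or self.n_puls < 0:
            raise ValueError("contig/gene/PUL counts out of range")
        if not (0 <= self.p_duplicated_pair <= 1 and 0 <= self.p_regulator <= 1):
            raise ValueError("probabilities must lie in [0,1]")
        if self.mean_gene_len <= 0 or self.mean_intergenic <= 0:
            raise ValueError("lengths must be > 0")
        lo, hi = self.pul_cazyme_range
        if not (0 <= lo <= hi):
            raise ValueError("pul_cazyme_range must satisfy 0 <= min <= max")


@dataclass(frozen=True)
class TruthRecord:
    pul_ordinal: int
    contig: str
    start: int
    end: int
    gene_ids: tuple[str, ...]
    substrate: str


# role tags used internally while laying out elements
_SUSC, _SUSD, _CAZ, _SULF, _HTCS, _ECF, _UNK = range(7)

#: filler genes inserted between elements; 3 unknowns exceed the default
#: max_gap_genes=2, so planted elements can never bleed into each other.
_SEPARATOR_GENES = 3


def _pair_hits(tag: int, gene_id: str, family: str | None, cfg: RunConfig) -> list[DomainHit]:
    rc = cfg.roles
    if tag == _SUSC:
        return [DomainHit(gene_id, "pfam", a) for a in sorted(rc.susc_require)]
    if tag == _SUSD:
        return [DomainHit(gene_id, "pfam", sorted(rc.susd_any)[0])]
    if tag == _CAZ:
        return [DomainHit(gene_id, "cazy", family)]
    if tag == _SULF:
        return [DomainHit(gene_id, "pfam", sorted(rc.sulfatase_any)[0])]
    if tag == _HTCS:
        return [DomainHit(gene_id, "pfam", a) for a in sorted(rc.htcs_require)]
    if tag == _ECF:
        return [DomainHit(gene_id, "pfam", a) for a in sorted(rc.ecf_sigma_require)]
    return []


def _pul_element(
    rng: np.random.Generator,
    spec: GenomeSimSpec,
    substrate: str,
    cfg: RunConfig,
) -> list[tuple[int, str | None]]:
    """Gene tags of one planted PUL, in transcription order."""
    core, accessory = cfg.substrates[substrate]
    pool = sorted(core)
    lo, hi = spec.pul_cazyme_range
    n_left = int(rng.integers(lo, hi + 1))
    n_right = int(rng.integers(lo, hi + 1))
    element: list[tuple[int, str | None]] = []
    if rng.random() < spec.p_regulator:
        element.append((_HTCS if rng.random() < 0.5 else _ECF, None))
    element += [(_CAZ, pool[int(rng.integers(len(pool)))]) for _ in range(n_left)]
    element += [(_SUSC, None)] * (2 if rng.random() < spec.p_duplicated_pair else 1)
    element += [(_SUSD, None)] * (2 if rng.random() < spec.p_duplicated_pair else 1)
    element += [(_CAZ, pool[int(rng.integers(len(pool)))]) for _ in range(n_right)]
    if substrate == "fucoidan" and rng.random() < 0.5:
        element.append((_SULF, None))
    return element


def generate_genome(
    spec: GenomeSimSpec,
    config: RunConfig | None = None,
) -> tuple[AnnotationBundle, list[TruthRecord]]:
    """Deterministic synthetic genome: (annotation bundle, planted truth)."""
    cfg = config or default_config()
    rng = np.random.default_rng(spec.seed)
    substrates = sorted(cfg.substrates)

    # build the element list: planted PULs plus decoys, each element a list of
    # (tag, family, strand_mode) gene tuples laid out later
    budget = spec.n_contigs * spec.genes_per_contig
    dr = spec.decoy_rates
    n_decoys = {
        "lone_susc": round(dr.lone_susc * budget),
        "lone_susd": round(dr.lone_susd * budget),
        "wrong_order_pair": round(dr.wrong_order_pair * budget),
        "opposite_strand_pair": round(dr.opposite_strand_pair * budget),
        "scattered_cazyme": round(dr.scattered_cazyme * budget),
    }

    elements: list[tuple[str, list[tuple[int, str | None]]]] = []
    for k in range(spec.n_puls):
        substrate = substrates[int(rng.integers(len(substrates)))]
        elements.append((f"pul:{substrate}", _pul_element(rng, spec, substrate, cfg)))
    all_families = sorted({f for core, acc in cfg.substrates.values() for f in core})
    for kind, count in n_decoys.items():
        for _ in range(count):
            if kind == "lone_susc":
                elements.append(("decoy", [(_SUSC, None)]))
            elif kind == "lone_susd":
                elements.append(("decoy", [(_SUSD, None)]))
            elif kind == "wrong_order_pair":
                elements.append(("decoy:wrong_order", [(_SUSD, None), (_SUSC, None)]))
            elif kind == "opposite_strand_pair":
                elements.append(("decoy:strand_split", [(_SUSC, None), (_SUSD, None)]))
            else:
                fam = all_families[int(rng.integers(len(all_families)))]
                elements.append(("decoy", [(_CAZ, fam)]))

    needed = sum(len(e) for _, e in elements) + _SEPARATOR_GENES * len(elements)
    if needed > budget:
        raise CapacityError(
            f"{len(elements)} elements need {needed} genes but the budget is "
            f"{budget} ({spec.n_contigs} x {spec.genes_per_contig})"
        )

    # shuffle elements, then distribute round-robin over contigs
    order = rng.permutation(len(elements))
    per_contig: list[list[int]] = [[] for _ in range(spec.n_contigs)]
    for pos, ei in enumerate(order):
        per_contig[pos % spec.n_contigs].append(int(ei))

    genes: list[GeneRecord] = []
    hits: list[DomainHit] = []
    truths: list[TruthRecord] = []
    ordinal = 0

    def gene_len() -> int:
        return max(90, int(rng.normal(spec.mean_gene_len, 0.2 * spec.mean_gene_len)))

    def intergenic() -> int:
        g = int(rng.normal(spec.mean_intergenic, 0.5 * spec.mean_intergenic))
        return min(max(1, g), max(1, 3 * spec.mean_intergenic))

    for ci in range(spec.n_contigs):
        contig = f"ctg{ci + 1:02d}"
        pos = 1 + int(rng.integers(50, 500))
        gnum = 0

        def place(tag: int, family: str | None, strand: str) -> GeneRecord:
            nonlocal pos, gnum
            gnum += 1
            length = gene_len()
            rec = GeneRecord(f"{contig}_g{gnum:04d}", contig, pos, pos + length - 1, strand)
            pos = rec.end + 1 + intergenic()
            genes.append(rec)
            hits.extend(_pair_hits(tag, rec.gene_id, family, cfg))
            return rec

        def separators() -> None:
            for _ in range(_SEPARATOR_GENES):
                place(_UNK, None, "+" if rng.random() < 0.5 else "-")

        for ei in per_contig[ci]:
            label, element = elements[ei]
            separators()
            if label.startswith("pul:"):
                substrate = label.split(":", 1)[1]
                strand = "+" if rng.random() < 0.5 else "-"
                layout = element if strand == "+" else list(reversed(element))
                placed = [place(tag, fam, strand) for tag, fam in layout]
                ordinal += 1
                truths.append(TruthRecord(
                    pul_ordinal=ordinal,
                    contig=contig,
                    start=min(g.start for g in placed),
                    end=max(g.end for g in placed),
                    gene_ids=tuple(g.gene_id for g in placed),
                    substrate=substrate,
                ))
            elif label == "decoy:strand_split":
                # SusC and SusD adjacent but on opposite strands
                place(element[0][0], None, "+")
                place(element[1][0], None, "-")
            elif label == "decoy:wrong_order":
                # coordinate order SusD then SusC, both plus strand
                strand = "+"
                for tag, fam in element:
                    place(tag, fam, strand)
            else:
                strand = "+" if rng.random() < 0.5 else "-"
                for tag, fam in element:
                    place(tag, fam, strand)
        # pad to the per-contig gene budget with unknown filler
        while gnum < spec.genes_per_contig:
            place(_UNK, None, "+" if rng.random() < 0.5 else "-")

    truths.sort(key=lambda t: (t.contig, t.start))
    truths = [replace(t, pul_ordinal=i + 1) for i, t in enumerate(truths)]
    bundle = AnnotationBundle(genes=genes, hits=hits, provenance=f"synthetic:seed={spec.seed}")
    return bundle, truths


def mirror_bundle(bundle: AnnotationBundle) -> AnnotationBundle:
    """Reverse-complement image: per contig, mirror coordinates and flip strands.

    Useful for strand-symmetry checks: loci called on the mirror must be the
    mirrored loci of the original.
    """
    length = {}
    for g in bundle.genes:
        length[g.contig] = max(length.get(g.contig, 0), g.end + 100)
    genes = [
        GeneRecord(
            g.gene_id, g.contig,
            length[g.contig] - g.end + 1,
            length[g.contig] - g.start + 1,
            "-" if g.strand == "+" else "+",
            g.product,
        )
        for g in bundle.genes
    ]
    return AnnotationBundle(genes=genes, hits=list(bundle.hits),
                            provenance=bundle.provenance + ";mirrored")


# ---------------------------------------------------------------------------
# fermentation series

#: (initial Mw Da, first-order decay /h) chosen per substrate so that the
#: 72 h endpoint sits at a realistic fraction of the start (e.g. ~77% for
#: laminarin, ~41% for the red-algal galactan)
MW_DEFAULTS = {
    "laminarin": (23600.0, 0.003605),
    "sodium_alginate": (5930.0, 0.003015),
    "fucoidan": (23000.0, 0.001487),
    "PHP": (433800.0, 0.012365),
}


@dataclass(frozen=True)
class FermentationDataset:
    substrate: str
    od: tuple[TimeSeries, ...]
    sugar: tuple[TimeSeries, ...]
    mw: tuple[TimeSeries, ...]

    def all_series(self) -> list[TimeSeries]:
        return [*self.od, *self.sugar, *self.mw]


def logistic(t: float, k: float, r: float, t0: float) -> float:
    return k / (1.0 + math.exp(-r * (t - t0)))


def generate_fermentation(
    seed: int,
    substrate: str = "laminarin",
    growth_k: float = 0.8,
    growth_r: float = 0.3,
    growth_t0: float = 12.0,
    s0: float = 10.0,
    sugar_decay: float = 0.02,
    m0: float | None = None,
    mw_decay: float | None = None,
    noise_sd: float = 0.02,
    times: tuple[float, ...] = DEFAULT_TIMES_H,
    n_replicates: int = 3,
) -> FermentationDataset:
    """Simulated triplicate OD600 / total-sugar / Mw trajectories.

    OD600 follows a logistic curve (carrying capacity ``growth_k`` OD,
    rate ``growth_r`` per h, midpoint ``growth_t0`` h); residual sugar and
    molecular weight decay exponentially from ``s0`` (mg/mL) and ``m0``
    (Da).  ``noise_sd`` is the relative (multiplicative) noise level; 0
    gives the exact mean trajectories.
    """
    if s0 <= 0:
        raise ValueError("s0 must be > 0")
    defaults = MW_DEFAULTS.get(substrate, MW_DEFAULTS["laminarin"])
    m0 = defaults[0] if m0 is None else m0
    mw_decay = defaults[1] if mw_decay is None else mw_decay
    if m0 <= 0:
        raise ValueError("m0 must be > 0")
    if growth_k <= 0 or growth_r <= 0 or sugar_decay < 0 or mw_decay < 0 or noise_sd < 0:
        raise ValueError("rate parameters must be positive (noise_sd >= 0)")
    rng = np.random.default_rng(seed)

    def noisy(mean: float) -> float:
        return max(0.0, mean * (1.0 + rng.normal(0.0, noise_sd))) if noise_sd else mean

    od, sugar, mw = [], [], []
    for rep in range(1, n_replicates + 1):
        rid = f"r{rep}"
        od.append(TimeSeries("OD600", substrate, tuple(
            (t, noisy(logistic(t, growth_k, growth_r, growth_t0))) for t in times
        ), rid))
        sugar.append(TimeSeries("total_sugar", substrate, tuple(
            (t, noisy(s0 * math.exp(-sugar_decay * t))) for t in times
        ), rid))
        mw.append(TimeSeries("Mw", substrate, tuple(
            (t, noisy(m0 * math.exp(-mw_decay * t))) for t in times
        ), rid))
    return FermentationDataset(substrate, tuple(od), tuple(sugar), tuple(mw))


# ---------------------------------------------------------------------------
# file emission (CLI simulate)


def write_truth_tsv(truths: list[TruthRecord], path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("pul_ordinal\tcontig\tstart\tend\tgene_ids\tsubstrate\n")
        for t in truths:
            fh.write(
                f"{t.pul_ordinal}\t{t.contig}\t{t.start}\t{t.end}\t"
                f"{';'.join(t.gene_ids)}\t{t.substrate}\n"
            )


def read_truth_tsv(path: str | Path) -> list[TruthRecord]:
    path = Path(path)
    truths = []
    with path.open() as fh:
        next(fh)
        for line in fh:
            if not line.strip():
                continue
            o, contig, start, end, gids, substrate = line.rstrip("\n").split("\t")
            truths.append(TruthRecord(
                int(o), contig, int(start), int(end),
                tuple(gids.split(";")), substrate,
            ))
    return truths


def write_synthetic_dataset(
    out_dir: str | Path,
    spec: GenomeSimSpec,
    config: RunConfig | None = None,
) -> dict[str, Path]:
    """Emit genome.gff3, domains.tsv, truth.tsv and fermentation.csv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle, truths = generate_genome(spec, config)
    paths = {
        "gff": out / "genome.gff3",
        "domains": out / "domains.tsv",
        "truth": out / "truth.tsv",
        "fermentation": out / "fermentation.csv",
    }
    write_gff(bundle, paths["gff"])
    write_domain_tsv(bundle.hits, paths["domains"])
    write_truth_tsv(truths, paths["truth"])
    series = []
    for i, substrate in enumerate(sorted(MW_DEFAULTS)):
        ds = generate_fermentation(seed=spec.seed + i, substrate=substrate)
        series.extend(ds.all_series())
    write_timeseries_csv(series, paths["fermentation"])
    return paths
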