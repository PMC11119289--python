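"""Role assignment, tandem-pair detection, locus extension, whole-genome calls."""

import itertools

import numpy as np
import pytest

from pulfinder.config import GapConfig, default_config
from pulfinder.pul_predictor import (
    Role,
    RegulatorKind,
    assign_roles,
    extend_to_pul,
    find_tandem_pairs,
    predict_puls,
)
from pulfinder.synthetic_data import mirror_bundle

import _oracles
from helpers import build_bundle, roles_of

CFG = default_config()


def _assign(bundle):
    return assign_roles(bundle, CFG.roles)


# ---------------------------------------------------------------------------
# assign_roles


@pytest.mark.parametrize("token, role, families, kind", [
    ("C", Role.SUSC, (), RegulatorKind.NONE),
    ("D", Role.SUSD, (), RegulatorKind.NONE),
    ("GH16", Role.CAZYME, ("GH16",), RegulatorKind.NONE),
    ("SULF", Role.SULFATASE, (), RegulatorKind.NONE),
    ("HTCS", Role.REGULATOR, (), RegulatorKind.HTCS),
    ("ECF", Role.REGULATOR, (), RegulatorKind.ECF_SIGMA),
    ("ANTI", Role.REGULATOR, (), RegulatorKind.ANTI_SIGMA),
    ("U", Role.UNKNOWN, (), RegulatorKind.NONE),
])
def test_single_signature_roles(token, role, families, kind):
    (r,) = _assign(build_bundle([token]))
    assert (r.role, r.families, r.regulator_kind) == (role, families, kind)


def test_susc_requires_both_domains():
    from pulfinder.annotation_io import AnnotationBundle, DomainHit, GeneRecord
    g = GeneRecord("g1", "c1", 1, 900, "+")
    one = sorted(CFG.roles.susc_require)[0]
    (r,) = _assign(AnnotationBundle([g], [DomainHit("g1", "x", one)]))
    assert r.role == Role.UNKNOWN


def test_conflict_priority_over_all_role_pairs(caplog):
    """Any two-role conflict resolves to the higher-priority role, with a warning."""
    from pulfinder.annotation_io import AnnotationBundle, DomainHit, GeneRecord
    from helpers import token_accessions
    priority = ["C", "D", "GH16", "SULF", "HTCS"]
    expected_role = {
        "C": Role.SUSC, "D": Role.SUSD, "GH16": Role.CAZYME,
        "SULF": Role.SULFATASE, "HTCS": Role.REGULATOR,
    }
    for a, b in itertools.combinations(priority, 2):
        g = GeneRecord("g1", "c1", 1, 900, "+")
        hits = [DomainHit("g1", "x", acc)
                for acc in token_accessions(a) + token_accessions(b)]
        with caplog.at_level("WARNING"):
            caplog.clear()
            (r,) = _assign(AnnotationBundle([g], hits))
        assert r.role == expected_role[a], f"{a}+{b}"
        assert "several roles" in caplog.text


# ---------------------------------------------------------------------------
# find_tandem_pairs


def _pairs(tokens, strands=None, **kw):
    bundle = build_bundle(tokens, strands=strands, **kw)
    return find_tandem_pairs(bundle.genes, _assign(bundle), CFG.gaps)


def test_minimal_pair_plus_strand():
    blocks = _pairs(["C", "D"])
    assert len(blocks) == 1
    assert blocks[0].susc_gene_ids == ("c1_g001",)
    assert blocks[0].susd_gene_ids == ("c1_g002",)


def test_strand_mismatch_gives_no_block():
    assert _pairs(["C", "D"], strands=["+", "-"]) == []


def test_duplicated_partners_absorbed_into_one_block():
    blocks = _pairs(["C", "C", "D", "D"])
    assert len(blocks) == 1
    assert len(blocks[0].susc_gene_ids) == 2
    assert len(blocks[0].susd_gene_ids) == 2


def test_wrong_order_on_plus_but_valid_on_minus():
    assert _pairs(["D", "C"], strands=["+", "+"]) == []
    blocks = _pairs(["D", "C"], strands=["-", "-"])
    assert len(blocks) == 1
    # transcription order on the minus strand runs right to left
    assert blocks[0].susc_gene_ids == ("c1_g002",)
    assert blocks[0].susd_gene_ids == ("c1_g001",)


def test_intervening_gene_breaks_adjacency_by_default():
    assert _pairs(["C", "GH16", "D"]) == []


def test_pair_gap_config_relaxes_adjacency():
    bundle = build_bundle(["C", "GH16", "D"])
    gaps = GapConfig(pair_max_gap_genes=1)
    blocks = find_tandem_pairs(bundle.genes, _assign(bundle), gaps)
    assert len(blocks) == 1


def test_pair_rule_matches_bruteforce_over_small_orderings():
    """Exhaustive role/strand orderings of <= 4 genes against the window oracle."""
    for n in (2, 3, 4):
        for tokens in itertools.product(["C", "D", "U"], repeat=n):
            for strands in itertools.product("+-", repeat=n):
                bundle = build_bundle(list(tokens), strands=list(strands))
                got = find_tandem_pairs(bundle.genes, _assign(bundle), CFG.gaps)
                oracle = _oracles.oracle_pair_windows(
                    bundle.genes, roles_of(list(tokens))
                )
                assert len(got) == len(oracle), (tokens, strands)


# ---------------------------------------------------------------------------
# extend_to_pul


def _extended(tokens, strands=None, **kw):
    bundle = build_bundle(tokens, strands=strands, **kw)
    roles = _assign(bundle)
    (block,) = find_tandem_pairs(bundle.genes, roles, CFG.gaps)
    return extend_to_pul(block, bundle.genes, roles, CFG.gaps)


def test_extension_absorbs_cazymes_and_regulator():
    pul = _extended(["GH16", "C", "D", "GH16", "HTCS"])
    assert len(pul.member_gene_ids) == 5
    assert pul.cazyme_families == ["GH16", "GH16"]
    assert pul.regulators == ["HTCS"]


def test_extension_stops_after_too_many_unknowns():
    pul = _extended(["GH16", "U", "U", "U", "C", "D"])
    assert len(pul.member_gene_ids) == 2
    assert pul.cazyme_free


def test_interior_unknowns_within_gap_are_retained():
    pul = _extended(["GH16", "U", "U", "C", "D"])
    assert len(pul.member_gene_ids) == 5


def test_extension_stops_at_large_intergenic_distance():
    gaps = [100, 100, 6000, 100, 100, 100]  # gap after the 3rd gene
    pul = _extended(["GH16", "GH16", "GH16", "C", "D", "GH16"], gaps=gaps)
    assert len(pul.member_gene_ids) == 3  # pair + right CAZyme only


def test_isolated_pair_is_cazyme_free():
    pul = _extended(["C", "D"])
    assert pul.cazyme_free
    assert pul.member_gene_ids == ["c1_g001", "c1_g002"]


# ---------------------------------------------------------------------------
# predict_puls


def test_no_susc_genes_means_no_puls():
    bundle = build_bundle(["GH16", "D", "PL8", "U"])
    assert predict_puls(bundle, CFG) == []


def test_adjacent_anchors_merge_into_one_locus():
    bundle = build_bundle(["C", "D", "U", "C", "D"])
    (pul,) = predict_puls(bundle, CFG)
    assert len(pul.pair_blocks) == 2
    assert len(pul.member_gene_ids) == 5


def test_numbering_follows_coordinates_across_contigs():
    import pulfinder.annotation_io as aio
    b1 = build_bundle(["C", "D"], contig="c2", start=1000)
    b2 = build_bundle(["C", "D"], contig="c1", start=5000)
    bundle = aio.AnnotationBundle(b1.genes + b2.genes, b1.hits + b2.hits)
    puls = predict_puls(bundle, CFG)
    assert [(p.pul_id, p.contig) for p in puls] == [("PUL1", "c1"), ("PUL2", "c2")]


def _random_small_bundle(rng, n_max=30):
    n = int(rng.integers(2, n_max + 1))
    tokens = list(rng.choice(
        ["C", "D", "GH16", "PL8", "U", "HTCS", "SULF"],
        size=n,
        p=[0.18, 0.18, 0.10, 0.08, 0.32, 0.07, 0.07],
    ))
    strands = list(rng.choice(["+", "-"], size=n))
    gaps = [6000 if rng.random() < 0.08 else int(rng.integers(20, 800))
            for _ in range(n)]
    return build_bundle(tokens, strands=strands, gaps=gaps), tokens


@pytest.mark.parametrize("seed", range(10))
def test_randomized_genomes_match_window_oracle(seed):
    rng = np.random.default_rng(1000 + seed)
    for _ in range(20):
        bundle, tokens = _random_small_bundle(rng)
        got = _oracles.puls_as_set(predict_puls(bundle, CFG))
        want = _oracles.oracle_predict(
            bundle.genes, roles_of(tokens),
            CFG.gaps.max_gap_genes, CFG.gaps.max_gap_bp,
        )
        assert got == want, tokens


def test_mirrored_genome_yields_mirrored_loci():
    rng = np.random.default_rng(42)
    for _ in range(20):
        bundle, _ = _random_small_bundle(rng)
        original = {frozenset(p.member_gene_ids) for p in predict_puls(bundle, CFG)}
        mirrored = {frozenset(p.member_gene_ids)
                    for p in predict_puls(mirror_bundle(bundle), CFG)}
        assert original == mirrored


def test_output_is_deterministic():
    bundle = build_bundle(["HTCS", "GH16", "C", "D", "PL8", "U", "C", "C", "D"])
    first = predict_puls(bundle, CFG)
    second = predict_puls(bundle, CFG)
    assert first == second
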