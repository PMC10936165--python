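"""Alignment scores, E-values, best hits, and essentiality transfer."""

import math

import numpy as np
import pytest

from genoslim.annotation import GeneFeature, GenomeAnnotation
from genoslim.errors import ValidationError
from genoslim.homology import (
    DISPENSABLE,
    ESSENTIAL,
    UNKNOWN,
    best_hits,
    estimate_evalue,
    local_align,
    read_hit_table,
    reciprocal_best_hits,
    transfer_essentiality,
)
from genoslim.synthetic import SynthesisSpec, generate_genome, generate_reference_proteome

from helpers import AA20, sw_affine_oracle


def random_protein(rng, lo=5, hi=25):
    return "".join(rng.choice(list(AA20), size=rng.integers(lo, hi + 1)))


# -- local alignment ---------------------------------------------------------


def test_identity_alignment_scores_match_sum():
    # four A<->A matches at BLOSUM62 +4
    assert local_align("AAAA", "AAAA") == 16.0


def test_zero_scoring_pairs_floor_at_zero():
    # A/C scores 0 in BLOSUM62; the empty local alignment wins
    assert local_align("AAAA", "CCCC") == 0.0


def test_alignment_score_is_symmetric():
    rng = np.random.default_rng(1)
    for _ in range(5):
        a, b = random_protein(rng), random_protein(rng)
        assert local_align(a, b) == local_align(b, a)


def test_unknown_residue_error_names_position():
    with pytest.raises(ValidationError, match="position 2"):
        local_align("MAZAA", "MAAA")


@pytest.mark.parametrize("seed", range(30))
def test_alignment_equals_brute_force_dp_oracle(seed):
    """PairwiseAligner scores equal an independently written affine-gap
    Smith-Waterman DP on random short pairs."""
    rng = np.random.default_rng(seed)
    a, b = random_protein(rng), random_protein(rng)
    assert local_align(a, b) == pytest.approx(sw_affine_oracle(a, b))


# -- E-values ----------------------------------------------------------------


def test_evalue_closed_forms():
    assert estimate_evalue(0, 1, 1, K=1.0, lam=math.log(2)) == pytest.approx(1.0)
    assert estimate_evalue(10, 1, 1, K=1.0, lam=math.log(2)) == pytest.approx(2.0**-10)


def test_evalue_linear_in_lengths_and_decreasing_in_score():
    e = estimate_evalue(50, 100, 200)
    assert estimate_evalue(50, 200, 200) == pytest.approx(2 * e)
    assert estimate_evalue(60, 100, 200) < e


def test_evalue_rejects_nonpositive_parameters():
    with pytest.raises(ValidationError):
        estimate_evalue(10, 0, 5)
    with pytest.raises(ValidationError):
        estimate_evalue(10, 5, 5, K=-1)


# -- best hits ---------------------------------------------------------------


def test_identical_subject_beats_random_ones():
    rng = np.random.default_rng(3)
    query = "".join(rng.choice(list(AA20), size=300))
    subjects = {f"s{i}": "".join(rng.choice(list(AA20), size=300)) for i in range(5)}
    subjects["match"] = query
    hits = best_hits({"q": query}, subjects)
    assert hits["q"].subject_id == "match"


def test_zero_cutoff_gives_empty_map():
    assert best_hits({"q": "MAAAAAAA"}, {"s": "MAAAAAAA"}, e_cutoff=0.0) == {}


def test_tie_breaks_by_score_then_lexicographic_id():
    seq = "M" + "A" * 199
    hits = best_hits({"q": seq}, {"sB": seq, "sA": seq})
    assert hits["q"].subject_id == "sA"


def test_hit_table_adapter_keeps_best_per_query(tmp_path):
    path = tmp_path / "hits.tsv"
    path.write_text("q1\tsA\t500\t1e-50\nq1\tsB\t600\t1e-60\nq2\tsC\t90\t1e-12\n")
    hits = read_hit_table(path)
    assert hits["q1"].subject_id == "sB"
    assert hits["q2"].evalue == pytest.approx(1e-12)


# -- reciprocal best hits ----------------------------------------------------


@pytest.fixture(scope="module")
def synthetic_pair():
    spec = SynthesisSpec(n_genes=50, mean_gene_len=240, seed=21, planted_regions=((8, 13),))
    ann, truth = generate_genome(spec)
    records, ortho = generate_reference_proteome(ann, 0.05, 21)
    queries = {f.locus_tag: f.protein for f in ann.features}
    return ann, truth, queries, dict(records), ortho


def test_rbh_identity_when_proteomes_equal(synthetic_pair):
    _, _, queries, _, _ = synthetic_pair
    small = dict(list(queries.items())[:10])
    assert reciprocal_best_hits(small, small) == {k: k for k in small}


def test_rbh_recovers_planted_orthologs(synthetic_pair):
    """>= 95% of true ortholog pairs survive 5% residue divergence."""
    _, _, queries, reference, ortho = synthetic_pair
    rbh = reciprocal_best_hits(queries, reference)
    recovered = sum(rbh.get(l) == r for l, r in ortho.items())
    assert recovered >= 0.95 * len(ortho)
    # one-to-one
    assert len(set(rbh.values())) == len(rbh)


def test_rbh_symmetric_under_swap(synthetic_pair):
    _, _, queries, reference, _ = synthetic_pair
    sub_q = dict(list(queries.items())[:15])
    fwd = reciprocal_best_hits(sub_q, reference)
    rev = reciprocal_best_hits(reference, sub_q)
    assert fwd == {b: a for a, b in rev.items() if a in reference and b in sub_q}


def test_unrelated_random_proteomes_yield_no_pairs():
    rng = np.random.default_rng(8)
    A = {f"a{i}": "".join(rng.choice(list(AA20), size=80)) for i in range(8)}
    B = {f"b{i}": "".join(rng.choice(list(AA20), size=80)) for i in range(8)}
    assert reciprocal_best_hits(A, B, e_cutoff=1e-10) == {}


def test_relaxing_cutoff_never_drops_best_hits(synthetic_pair):
    _, _, queries, reference, _ = synthetic_pair
    sub_q = dict(list(queries.items())[:12])
    strict = best_hits(sub_q, reference, e_cutoff=1e-10)
    loose = best_hits(sub_q, reference, e_cutoff=1e-2)
    for q, hit in strict.items():
        assert loose[q].subject_id == hit.subject_id


# -- transfer ----------------------------------------------------------------


def small_annotation():
    return GenomeAnnotation(
        "chr",
        3000,
        [
            GeneFeature("gA", 0, 900, "+", protein="M" + "A" * 10),
            GeneFeature("gB", 1000, 1900, "+", protein="M" + "C" * 10),
            GeneFeature("gC", 2000, 2900, "+", protein="M" + "D" * 10),
        ],
    )


def test_transfer_label_rules():
    ann = small_annotation()
    ess = transfer_essentiality(ann, {"gA": "rA", "gB": "rB"}, {"rA"})
    assert ess.labels == {"gA": ESSENTIAL, "gB": DISPENSABLE, "gC": UNKNOWN}
    assert ess.provenance == {"gA": "rA", "gB": "rB", "gC": None}


def test_transfer_warns_on_essentials_missing_from_reference():
    ann = small_annotation()
    with pytest.warns(UserWarning, match="absent"):
        transfer_essentiality(ann, {"gA": "rA"}, {"rA", "ghost"}, reference_ids={"rA"})


def test_full_pipeline_label_accuracy_at_low_divergence():
    """At 2% divergence every mapped locus gets its true label."""
    spec = SynthesisSpec(n_genes=40, mean_gene_len=210, seed=13, mutation_rate=0.02,
                         planted_regions=((6, 10),))
    ann, truth = generate_genome(spec)
    records, ortho = generate_reference_proteome(ann, 0.02, 13)
    queries = {f.locus_tag: f.protein for f in ann.features}
    rbh = reciprocal_best_hits(queries, dict(records))
    ref_essentials = {ortho[l] for l, lab in truth.labels.items() if lab == ESSENTIAL}
    ess = transfer_essentiality(ann, rbh, ref_essentials)
    mapped = [l for l in ann.loci() if ess.provenance[l] is not None]
    assert mapped  # transfer actually happened
    assert all(ess.labels[l] == truth.labels[l] for l in mapped)
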