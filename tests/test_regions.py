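"""Region search: hand-enumerated cases, oracle equivalence, tie rules."""

import numpy as np
import pytest

from genoslim.annotation import GeneFeature, GenomeAnnotation
from genoslim.errors import ValidationError
from genoslim.fba import apply_deletions, fba
from genoslim.homology import EssentialityMap
from genoslim.regions import (
    SearchConfig,
    _SearchContext,
    brute_force_regions,
    enumerate_regions,
    longest_dispensable_window,
    region_length_footnote,
    window_is_deletable,
)

from helpers import planted_windows, random_instance, region_tuples


# -- six-gene hand enumeration ----------------------------------------------


def test_longest_window_is_the_planted_pair(six_gene_setup):
    ann, ess, model = six_gene_setup
    region = longest_dispensable_window(ann, ess, model)
    assert (region.first_index, region.last_index) == (1, 2)
    assert (region.first_locus, region.last_locus) == ("g2", "g3")
    assert region.length_span == 2000


def test_brute_force_matches_hand_enumeration(six_gene_setup):
    ann, ess, model = six_gene_setup
    regions = brute_force_regions(ann, ess, model)
    assert region_tuples(regions) == [(1, 1, 2, 2000), (2, 4, 4, 1000)]


def test_enumerate_matches_brute_force_on_toy(six_gene_setup):
    ann, ess, model = six_gene_setup
    assert region_tuples(enumerate_regions(ann, ess, model)) == region_tuples(
        brute_force_regions(ann, ess, model)
    )


def test_all_essential_genome_has_no_window(six_gene_setup):
    ann, _, model = six_gene_setup
    labels = {f.locus_tag: "essential" for f in ann.features}
    all_ess = EssentialityMap(labels, {l: None for l in labels})
    assert longest_dispensable_window(ann, all_ess, model) is None
    assert enumerate_regions(ann, all_ess, model) == []
    assert brute_force_regions(ann, all_ess, model) == []


def test_window_containing_essential_short_circuits_fba(six_gene_setup, monkeypatch):
    ann, ess, model = six_gene_setup
    ctx = _SearchContext(ann, ess, model, SearchConfig())
    monkeypatch.setattr(
        _SearchContext, "growth_after", lambda *_: pytest.fail("FBA invoked")
    )
    assert window_is_deletable(ann, ess, model, (0, 2), _ctx=ctx) is False
    assert window_is_deletable(ann, ess, model, (0, 5), _ctx=ctx) is False


def test_planted_window_is_deletable(six_gene_setup):
    ann, ess, model = six_gene_setup
    assert window_is_deletable(ann, ess, model, (1, 2)) is True


def test_window_outside_annotation_rejected(six_gene_setup):
    ann, ess, model = six_gene_setup
    with pytest.raises(ValidationError):
        window_is_deletable(ann, ess, model, (4, 6))


def test_equal_length_optima_return_leftmost():
    """g2..g3 and the symmetric g5..g6 tie; the leftmost wins."""
    from genoslim.models import ModelDocument, Reaction

    features = [
        GeneFeature(f"g{i + 1}", i * 1000, (i + 1) * 1000, "+", protein="MA")
        for i in range(7)
    ]
    ann = GenomeAnnotation("chr", 7000, features)
    labels = {f"g{i + 1}": "dispensable" for i in range(7)}
    for locus in ("g1", "g4", "g7"):
        labels[locus] = "essential"
    ess = EssentialityMap(labels, {l: None for l in labels})
    model7 = ModelDocument(
        "toy7",
        {"C": "c", "P": "c"},
        [
            Reaction("R_uptake", {"C": 1.0}, 0.0, 10.0, ""),
            Reaction("R_main", {"C": -1.0, "P": 1.0}, 0.0, 1000.0, "g1 and g4 and g7"),
            Reaction("R_bio", {"P": -10.0}, 0.0, 1000.0, ""),
        ],
        "R_bio",
    )
    for engine in ("scan", "milp"):
        region = longest_dispensable_window(
            ann, ess, model7, SearchConfig(engine=engine)
        )
        assert (region.first_index, region.last_index) == (1, 2)


# -- footnote length convention ---------------------------------------------


def footnote_annotation():
    return GenomeAnnotation(
        "chr",
        10000,
        [
            GeneFeature("g1", 100, 1000, "+", protein="MA"),
            GeneFeature("g5", 4100, 5000, "+", protein="MA"),
            GeneFeature("gM", 8000, 9000, "-", protein="MA"),
        ],
    )


def test_footnote_length_is_start_site_distance():
    ann = footnote_annotation()
    assert region_length_footnote(ann, "g1", "g5") == 4000
    assert region_length_footnote(ann, "g1", "g1") == 0


def test_footnote_minus_strand_start_site_is_high_coordinate():
    ann = footnote_annotation()
    assert region_length_footnote(ann, "g1", "gM") == 9000 - 100
    assert region_length_footnote(ann, "g1", "gM", strand_aware=False) == 8000 - 100


def test_footnote_missing_locus_errors():
    with pytest.raises(ValidationError):
        region_length_footnote(footnote_annotation(), "g1", "ghost")


# -- oracle equivalence and properties --------------------------------------


@pytest.mark.parametrize("seed", range(8))
def test_enumerate_equals_brute_force_on_random_instances(seed):
    """Same windows, same lengths, same ranks as exhaustive enumeration."""
    _, ann, truth, model = random_instance(seed, n_genes=int(60 + 20 * seed))
    cfg = SearchConfig(min_region_len=1)
    assert region_tuples(enumerate_regions(ann, truth, model, cfg)) == region_tuples(
        brute_force_regions(ann, truth, model, cfg)
    )


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_milp_engine_equals_scan_engine(seed):
    """The MILP formulation and the monotone scan return identical regions."""
    _, ann, truth, model = random_instance(seed, n_genes=60)
    scan = enumerate_regions(ann, truth, model, SearchConfig(engine="scan", max_regions=4))
    milp = enumerate_regions(ann, truth, model, SearchConfig(engine="milp", max_regions=4))
    assert region_tuples(scan) == region_tuples(milp)


def test_planted_regions_recovered_in_size_order():
    spec, ann, truth, model = random_instance(42, n_genes=150)
    min_len = 4 * (150 + 30)  # above any background run, below planted sizes
    regions = enumerate_regions(ann, truth, model, SearchConfig(min_region_len=min_len))
    got = sorted((r.first_index, r.last_index) for r in regions)
    assert got == sorted(planted_windows(spec))
    spans = [r.length_span for r in regions]
    assert spans == sorted(spans, reverse=True)


def test_regions_disjoint_and_nonincreasing_across_seeds():
    for seed in range(10):
        _, ann, truth, model = random_instance(300 + seed, n_genes=80)
        regions = enumerate_regions(ann, truth, model)
        spans = [r.length_span for r in regions]
        assert spans == sorted(spans, reverse=True)
        windows = sorted(r.gene_window() for r in regions)
        for (a1, b1), (a2, b2) in zip(windows, windows[1:]):
            assert b1 < a2


def test_reported_regions_preserve_max_growth():
    """Post-hoc validation: deleting each reported region's genes keeps
    mu >= mu_fraction * mu_max."""
    _, ann, truth, model = random_instance(7, n_genes=100)
    cfg = SearchConfig()
    mu_max = fba(model).objective_value
    for r in enumerate_regions(ann, truth, model, cfg):
        genes = {ann.features[i].locus_tag for i in range(r.first_index, r.last_index + 1)}
        mu = fba(apply_deletions(model, genes)).objective_value
        assert mu >= cfg.mu_fraction * mu_max


def test_infeasible_window_implies_infeasible_superwindows():
    _, ann, truth, model = random_instance(17, n_genes=60)
    ctx = _SearchContext(ann, truth, model, SearchConfig())
    rng = np.random.default_rng(17)
    n = len(ann)
    checked = 0
    for _ in range(200):
        i = int(rng.integers(0, n - 1))
        j = int(rng.integers(i, n))
        if not ctx.feasible(i, j):
            ii, jj = max(0, i - 1), min(n - 1, j + 1)
            assert not ctx.feasible(ii, jj)
            checked += 1
    assert checked > 10


def test_max_regions_limits_output():
    _, ann, truth, model = random_instance(5, n_genes=60)
    all_regions = enumerate_regions(ann, truth, model)
    top1 = enumerate_regions(ann, truth, model, SearchConfig(max_regions=1))
    assert region_tuples(top1) == region_tuples(all_regions[:1])


def test_min_region_len_stops_search():
    _, ann, truth, model = random_instance(5, n_genes=60)
    huge = enumerate_regions(ann, truth, model, SearchConfig(min_region_len=10**9))
    assert huge == []


def test_cumulative_mode_reapplies_deletions():
    _, ann, truth, model = random_instance(9, n_genes=60)
    cumulative = enumerate_regions(ann, truth, model, SearchConfig(cumulative=True, max_regions=3))
    plain = enumerate_regions(ann, truth, model, SearchConfig(max_regions=3))
    # toy models keep non-essential deletions neutral, so both agree here
    assert region_tuples(cumulative) == region_tuples(plain)


def test_brute_force_guard_on_large_annotations():
    _, ann, truth, model = random_instance(2, n_genes=60)
    with pytest.raises(ValidationError, match="brute force"):
        brute_force_regions(ann, truth, model, max_genes=10)
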