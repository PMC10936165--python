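"""Cas3 deletion windows, simulated libraries, and tiling-PCR inference."""

import numpy as np
import pytest
from scipy import stats

from genoslim.annotation import GeneFeature, GenomeAnnotation
from genoslim.cas3 import (
    DeletionEvent,
    PrimerPair,
    band_matrix,
    deletion_length_histogram,
    infer_deletion_bounds,
    make_tiling_panel,
    max_deletion_window,
    simulate_deletion_library,
    simulate_tiling_pcr,
)
from genoslim.errors import ValidationError
from genoslim.homology import EssentialityMap


def flank_setup():
    """Two essential genes at the genome ends, dispensables between."""
    features = [
        GeneFeature("g1", 0, 1000, "+", protein="MA"),
        GeneFeature("g3", 4000, 5000, "+", protein="MA"),
        GeneFeature("g6", 9000, 10000, "+", protein="MA"),
    ]
    ann = GenomeAnnotation("chr", 10000, features)
    labels = {"g1": "essential", "g3": "dispensable", "g6": "essential"}
    return ann, EssentialityMap(labels, {l: None for l in labels})


# -- deletion window ---------------------------------------------------------


def test_window_spans_between_flanking_essentials():
    ann, ess = flank_setup()
    assert max_deletion_window(ann, ess, 5000) == (1000, 9000)


def test_window_without_protected_genes_is_whole_sequence():
    ann, _ = flank_setup()
    labels = {l: "dispensable" for l in ann.loci()}
    free = EssentialityMap(labels, {l: None for l in labels})
    assert max_deletion_window(ann, free, 5000) == (0, 10000)


def test_protospacer_inside_protected_gene_is_an_error():
    ann, ess = flank_setup()
    with pytest.raises(ValidationError, match="protected"):
        max_deletion_window(ann, ess, 500)


def test_protect_unknown_flag_narrows_window():
    ann, _ = flank_setup()
    labels = {"g1": "essential", "g3": "unknown", "g6": "essential"}
    ess = EssentialityMap(labels, {l: None for l in labels})
    assert max_deletion_window(ann, ess, 6000) == (1000, 9000)
    assert max_deletion_window(ann, ess, 6000, protect_unknown=True) == (5000, 9000)


# -- simulated library -------------------------------------------------------


def test_events_respect_window_and_contain_protospacer():
    events = simulate_deletion_library((1000, 9000), 5000, 1000, seed=1)
    for e in events:
        assert 1000 <= e.left_end <= 5000 < e.right_end <= 9000


def test_simulated_events_respect_flanking_essential_window():
    ann, ess = flank_setup()
    window = max_deletion_window(ann, ess, 2500)
    for seed in range(5):
        for e in simulate_deletion_library(window, 2500, 100, seed=seed):
            assert window[0] <= e.left_end and e.right_end <= window[1]


def test_escaper_probability_one_gives_zero_lengths():
    events = simulate_deletion_library((0, 1000), 500, 50, escaper_prob=1.0, seed=2)
    assert all(e.length == 0 for e in events)


def test_library_deterministic_per_seed():
    kw = dict(window=(1000, 9000), protospacer_pos=4000, n=100)
    assert simulate_deletion_library(**kw, seed=5) == simulate_deletion_library(**kw, seed=5)
    assert simulate_deletion_library(**kw, seed=5) != simulate_deletion_library(**kw, seed=6)


def test_uniform_mean_length_matches_closed_form():
    """E[length] = E[left extent] + E[right extent] for independent
    uniform draws over [0, L_left] and [1, L_right]."""
    wl, wr, pos, n = 1000, 9000, 4000, 4000
    events = simulate_deletion_library((wl, wr), pos, n, seed=3)
    expected = (pos - wl) / 2 + (1 + wr - pos) / 2
    sigma = np.sqrt(((pos - wl) ** 2 + (wr - pos) ** 2) / 12 / n)
    mean = np.mean([e.length for e in events])
    assert abs(mean - expected) < 3 * sigma


def test_geometric_model_produces_shorter_deletions():
    uniform = simulate_deletion_library((0, 20000), 10000, 500, seed=4)
    geom = simulate_deletion_library((0, 20000), 10000, 500, "geometric", p=1e-3, seed=4)
    assert np.mean([e.length for e in geom]) < np.mean([e.length for e in uniform])


def test_invalid_model_parameters_rejected():
    with pytest.raises(ValidationError):
        simulate_deletion_library((0, 100), 50, 10, "geometric", p=None)
    with pytest.raises(ValidationError):
        simulate_deletion_library((0, 100), 200, 10)


# -- histogram ---------------------------------------------------------------


def test_histogram_bins_and_frequencies():
    events = [DeletionEvent(600, 500, 1000), DeletionEvent(600, 100, 1600),
              DeletionEvent(900, 250, 1750)]
    # lengths 500, 1500, 1500
    hist = deletion_length_histogram(events, 1000)
    assert list(hist["count"]) == [1, 2]
    assert list(hist["bin_start"]) == [0, 1000]
    assert hist["frequency"].sum() == pytest.approx(1.0)


def test_histogram_empty_events():
    assert deletion_length_histogram([], 1000).empty


def test_histogram_counts_conserve_n():
    events = simulate_deletion_library((0, 30000), 15000, 500, seed=9)
    hist = deletion_length_histogram(events, 2000)
    assert hist["count"].sum() == 500


def test_histogram_of_uniform_draws_is_flat():
    """10^4 uniform lengths -> chi-square GOF accepts flatness."""
    rng = np.random.default_rng(12)
    lengths = rng.integers(0, 10000, size=10_000)
    events = [DeletionEvent(0, 0, int(l)) if l else DeletionEvent(0, 0, 0) for l in lengths]
    hist = deletion_length_histogram(events, 1000)
    _, p = stats.chisquare(hist["count"])
    assert p > 1e-3


# -- tiling PCR --------------------------------------------------------------


def test_intact_short_amplicon_gives_band():
    pp = PrimerPair("P1", 1000, 1020, 2480, 2500)
    no_del = DeletionEvent(5000, 5000, 5000)
    assert simulate_tiling_pcr(no_del, [pp]) == [True]


def test_primer_inside_deletion_kills_band():
    pp = PrimerPair("P1", 1000, 1020, 2480, 2500)
    event = DeletionEvent(2400, 2300, 2600)  # rev primer destroyed
    assert simulate_tiling_pcr(event, [pp]) == [False]


def test_large_wt_span_amplifies_only_after_deletion():
    """A 40 kb span fails in WT (cap 20 kb) but yields a ~7 kb product
    across a 33 kb deletion."""
    pp = PrimerPair("Pconf", 0, 20, 39980, 40000)
    wt = DeletionEvent(20000, 20000, 20000)
    sg = DeletionEvent(20000, 3500, 36500)  # 33 kb deleted between primers
    assert simulate_tiling_pcr(wt, [pp], max_amplicon=20000) == [False]
    assert simulate_tiling_pcr(sg, [pp], max_amplicon=20000) == [True]
    assert pp.expected_amplicon - sg.length == 7000


def test_band_matrix_orders_columns_by_position():
    panel = make_tiling_panel(0, 8000, spacing=2000)
    events = simulate_deletion_library((0, 8000), 4000, 10, seed=1)
    bm = band_matrix(events, panel)
    assert list(bm.columns) == ["P1", "P2", "P3", "P4"]
    assert bm.shape == (10, 4)


# -- inference ---------------------------------------------------------------


def test_all_bands_present_means_no_evidence():
    panel = make_tiling_panel(0, 8000, spacing=2000)
    bounds = infer_deletion_bounds([True] * 4, panel)
    assert bounds.outer is None and bounds.inner is None
    assert not bounds.contradictory


def test_single_absent_band_localizes_between_flanks():
    panel = make_tiling_panel(0, 8000, spacing=2000)
    bounds = infer_deletion_bounds([True, False, True, True], panel, seq_length=8000)
    # deletion confined to the gap between certified-intact primers
    assert bounds.outer == (2000, 4000)
    # a single implicated band cannot certify any specific deleted bp
    assert bounds.inner is None


def test_multi_band_absence_yields_inner_interval():
    panel = make_tiling_panel(0, 10000, spacing=2000)
    event = DeletionEvent(5000, 2500, 7500)
    row = simulate_tiling_pcr(event, panel)
    bounds = infer_deletion_bounds(row, panel, seq_length=10000)
    assert bounds.inner is not None
    il, ir = bounds.inner
    ol, orr = bounds.outer
    assert ol <= event.left_end <= il < ir <= event.right_end <= orr


def test_contradictory_pattern_flagged():
    panel = [
        PrimerPair("Pleft", 0, 20, 1980, 2000),
        PrimerPair("Pbig", 0, 20, 5980, 6000),
        PrimerPair("Pright", 4000, 4020, 5980, 6000),
    ]
    # Pbig absent although both its primers are certified by present bands
    bounds = infer_deletion_bounds([True, False, True], panel, seq_length=8000)
    assert bounds.contradictory


@pytest.mark.parametrize("seed", range(4))
def test_round_trip_inference_brackets_truth(seed):
    """inner ⊆ true deletion ⊆ outer for every informative colony of a
    200-event library screened with a 2 kb panel."""
    window, pos = (1000, 17000), 9000
    panel = make_tiling_panel(*window, spacing=2000)
    events = simulate_deletion_library(window, pos, 200, seed=seed)
    bm = band_matrix(events, panel)
    for i, e in enumerate(events):
        bounds = infer_deletion_bounds(list(bm.iloc[i]), panel, seq_length=18000)
        assert not bounds.contradictory
        if bounds.outer is None:
            # no primer was destroyed; nothing to bracket
            destroyed = any(
                e.overlaps(p.fwd_start, p.fwd_end) or e.overlaps(p.rev_start, p.rev_end)
                for p in panel
            )
            assert not destroyed
            continue
        assert bounds.outer[0] <= e.left_end and e.right_end <= bounds.outer[1]
        if bounds.inner is not None:
            assert e.left_end <= bounds.inner[0] and bounds.inner[1] <= e.right_end
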