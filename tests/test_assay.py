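import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import snpauth as sa
from snpauth.assay import replicate_error_rate, strain_sdp

NAN = np.nan


@pytest.mark.parametrize(
    "calls, expected",
    [
        ([0, 0, 2, 2], 0.5),
        ([0, 0, 0, 0], 0.0),
        ([0, 1, 2, 2], 0.375),  # p = 5/8
    ],
)
def test_minor_allele_frequency(calls, expected):
    assert sa.minor_allele_frequency(calls) == pytest.approx(expected)


def test_maf_all_na_is_error():
    with pytest.raises(ValueError):
        sa.minor_allele_frequency([NAN, NAN])


def test_replicate_consistency_rules():
    calls = np.array(
        [[0, 0], [0, 1], [NAN, NAN]]  # marker 0: {0,0,NA}; marker 1: {0,1,NA}
    )
    ok = sa.replicate_consistency(calls, ["g1", "g1", "g1"])
    assert ok.tolist() == [True, False]
    # no replicate groups: vacuously consistent
    assert sa.replicate_consistency(calls, [None, None, None]).all()


@pytest.mark.parametrize(
    "a, b, expected",
    [
        ([0, 0, 2, 2], [0, 0, 2, 2], 1.0),
        ([0, 0, 2, 2], [0, 2, 0, 2], 0.0),
        ([0, 0, 2, 2], [0, 0, 0, 2], 1 / 3),
    ],
)
def test_pairwise_r2_hand_values(a, b, expected):
    assert sa.pairwise_r2(a, b) == pytest.approx(expected, abs=1e-12)


def test_pairwise_r2_monomorphic_is_nan():
    assert np.isnan(sa.pairwise_r2([0, 0, 0], [0, 2, 2]))


def test_pairwise_r2_matches_brute_force_oracle(rng):
    def oracle(a, b):
        both = np.isfinite(a) & np.isfinite(b)
        a, b = a[both], b[both]
        num = ((a - a.mean()) * (b - b.mean())).sum()
        den = np.sqrt(((a - a.mean()) ** 2).sum() * ((b - b.mean()) ** 2).sum())
        return (num / den) ** 2

    for _ in range(100):
        n = rng.integers(3, 51)
        a = rng.choice([0.0, 1.0, 2.0, NAN], size=n, p=[0.4, 0.15, 0.4, 0.05])
        b = rng.choice([0.0, 1.0, 2.0, NAN], size=n, p=[0.4, 0.15, 0.4, 0.05])
        got = sa.pairwise_r2(a, b)
        both = np.isfinite(a) & np.isfinite(b)
        if both.sum() < 2 or len(set(a[both])) < 2 or len(set(b[both])) < 2:
            assert np.isnan(got)
        else:
            assert got == pytest.approx(oracle(a, b), abs=1e-12)


@pytest.mark.parametrize(
    "a, b, expected",
    [
        ([0, 0, 2, 2], [2, 2, 0, 0], True),  # dosage complement
        ([0, 0, 2, 2], [0, 2, 0, 2], False),
        ([0, NAN, 2, 2], [0, 0, 2, 2], False),  # NA sets differ
        ([0, NAN, 2, 2], [2, NAN, 0, 0], True),
    ],
)
def test_sdp_equal(a, b, expected):
    assert sa.sdp_equal(a, b) is expected


def _design_db():
    """Hand-built panel exercising every selection criterion.

    4 strains, replicated; markers on chromosome 1 at increasing positions
    plus one X-linked marker.
    """
    strains = {"A": 0, "B": 1, "C": 2, "D": 3}
    # per-marker SDP over strains A..D (dosages)
    marker_defs = [
        ("mX", "X", 100, [0, 0, 2, 2]),          # criterion 1: not autosomal
        ("m_mono", "1", 50, [0, 0, 0, 0]),        # criterion 3: fixed
        ("m1", "1", 100, [0, 0, 2, 2]),           # kept
        ("m2", "1", 200, [0, 0, 2, 2]),           # LD with m1, same SDP -> dropped
        ("m3", "1", 300, [2, 2, 0, 0]),           # complement of m1 -> same SDP -> dropped
        ("m4", "1", 400, [0, 2, 0, 2]),           # different SDP, kept despite LD
        ("m5", "1", 500, [0, 2, 2, 0]),           # kept
    ]
    sample_ids, rows, anns = [], [], {}
    for strain in strains:
        for r in (1, 2):
            sid = f"{strain}{r}"
            sample_ids.append(sid)
            rows.append([defs[3][strains[strain]] for defs in marker_defs])
            anns[sid] = sa.SampleAnnotation(
                sid, "reference", strain_label=strain, replicate_group=strain
            )
    calls = np.array(rows, dtype=np.float32)
    # criterion 2: marker with call rate 6/8 = 0.75 (below the 0.8 bar)
    low_cr = np.array([[0], [0], [2], [2], [NAN], [NAN], [0], [2]], dtype=np.float32)
    # criterion 4: replicate-inconsistent marker (A1 != A2)
    incons = np.array([[0], [2], [0], [0], [2], [2], [0], [0]], dtype=np.float32)
    calls = np.hstack([calls, low_cr, incons])
    markers = {d[0]: sa.MarkerAnnotation(d[0], d[1], d[2], ("A", "G")) for d in marker_defs}
    markers["m_lowcr"] = sa.MarkerAnnotation("m_lowcr", "1", 600, ("A", "G"))
    markers["m_incons"] = sa.MarkerAnnotation("m_incons", "1", 700, ("A", "G"))
    mids = [d[0] for d in marker_defs] + ["m_lowcr", "m_incons"]
    return sa.Database(sa.GenotypeMatrix(sample_ids, mids, calls), markers, anns)


def test_select_assay_markers_applies_all_criteria():
    db = _design_db()
    assay = sa.select_assay_markers(db)
    assert assay.informative_markers == ["m1", "m4", "m5"]
    reasons = dict(
        zip(assay.filter_log["marker_id"], assay.filter_log["exclusion_reason"])
    )
    assert reasons["mX"] == "not_autosomal"
    assert reasons["m_lowcr"] == "low_call_rate"
    assert reasons["m_mono"] == "monomorphic"
    assert reasons["m_incons"] == "replicate_inconsistent"
    assert reasons["m2"] == "ld_redundant"
    assert reasons["m3"] == "ld_redundant"  # complement SDPs count as identical
    assert assay.error_rate_E == pytest.approx(0.032)


def test_selection_invariant_to_marker_row_order(small_panel):
    base = sa.select_assay_markers(small_panel)
    rng = np.random.default_rng(7)
    perm = rng.permutation(len(small_panel.genotypes.markers))
    markers = [small_panel.genotypes.markers[j] for j in perm]
    shuffled = sa.Database(
        sa.GenotypeMatrix(
            small_panel.genotypes.samples, markers, small_panel.genotypes.calls[:, perm]
        ),
        small_panel.markers,
        small_panel.samples,
    )
    assert sa.select_assay_markers(shuffled).informative_markers == base.informative_markers


def test_retained_adjacent_pairs_satisfy_criterion_five(small_panel, small_assay):
    """Every physically adjacent retained pair has r^2 < 0.25 or distinct SDPs."""
    db = small_panel
    refs = [db.genotypes.sample_position(s) for s in db.reference_ids()]
    by_chrom: dict[str, list[str]] = {}
    for m in small_assay.informative_markers:
        by_chrom.setdefault(db.markers[m].chromosome, []).append(m)
    checked = 0
    for ms in by_chrom.values():
        ms = sorted(ms, key=lambda m: db.markers[m].position_bp)
        for m1, m2 in zip(ms, ms[1:]):
            r2 = sa.pairwise_r2(
                db.genotypes.column(m1)[refs], db.genotypes.column(m2)[refs]
            )
            ok = (not np.isfinite(r2)) or r2 < 0.25 or not sa.sdp_equal(
                strain_sdp(db, m1), strain_sdp(db, m2)
            )
            assert ok
            checked += 1
    assert checked > 50


def test_outbred_consistent_subset(small_panel, small_assay):
    sub = set(small_assay.outbred_consistent_markers)
    assert sub <= set(small_assay.informative_markers)
    # each outbred line's calls must agree on every subset marker
    for line, ids in small_panel.outbred_lines().items():
        rows = [small_panel.genotypes.sample_position(s) for s in ids]
        for m in small_assay.outbred_consistent_markers:
            col = small_panel.genotypes.column(m)[rows]
            col = col[np.isfinite(col)]
            assert col.size == 0 or (col == col[0]).all()
    # without outbred samples the subset equals the candidate set
    inbred_only = sa.make_reference_panel(sa.PanelSpec(n_strains=4, n_markers=50, seed=2))
    assert sa.outbred_consistent_subset(inbred_only, ["m000001", "m000002"]) == [
        "m000001", "m000002",
    ]


@pytest.mark.parametrize(
    "p1, p2, expected",
    [
        (0, 2, 1.0), (2, 0, 1.0), (0, 0, 0.0), (2, 2, 2.0),
        (1, 0, NAN), (NAN, 2, NAN),
    ],
)
def test_impute_f1_rules(p1, p2, expected):
    got = sa.impute_f1([p1], [p2])[0]
    if np.isnan(expected):
        assert np.isnan(got)
    else:
        assert got == expected


@given(st.integers(2, 8))
@settings(deadline=None, max_examples=8)
def test_f1_panel_size_and_mendelian_consistency(n_parents):
    db = sa.make_reference_panel(sa.PanelSpec(n_strains=max(n_parents, 2), n_markers=60, seed=5))
    parents = db.genotypes.samples[:n_parents]
    out = sa.generate_insilico_f1_panel(db, parents)
    f1_ids = out.genotypes.samples[len(db.genotypes.samples):]
    assert len(f1_ids) == n_parents * (n_parents - 1) // 2
    for (i, j), fid in zip(itertools.combinations(range(n_parents), 2), f1_ids):
        f1 = out.genotypes.row(fid)
        p1 = db.genotypes.row(parents[i])
        p2 = db.genotypes.row(parents[j])
        called = np.isfinite(f1)
        # every imputed call is the mean of two homozygous parents
        assert np.array_equal(f1[called], ((p1 + p2) / 2)[called])


def test_f1_label_collision_gets_suffix():
    db = sa.make_reference_panel(sa.PanelSpec(n_strains=3, n_markers=30, seed=1))
    once = sa.generate_insilico_f1_panel(db, db.genotypes.samples[:2])
    twice = sa.generate_insilico_f1_panel(once, db.genotypes.samples[:2])
    labels = twice.genotypes.samples[-2:]
    assert labels[0] != labels[1] and labels[1].endswith("_2")
    assert any("collision" in line for line in twice.provenance)


def test_replicate_error_rate_tracks_injected_discordance():
    db = sa.make_reference_panel(
        sa.PanelSpec(n_strains=6, n_markers=2000, n_replicates=2, seed=9)
    )
    noisy = sa.perturb_calls(db.genotypes.calls, sa.NoiseSpec(call_error=0.01, no_call_rate=0, seed=4))
    db2 = sa.Database(
        sa.GenotypeMatrix(db.genotypes.samples, db.genotypes.markers, noisy),
        db.markers, db.samples,
    )
    e = replicate_error_rate(db2)
    # each marker is inconsistent if either replicate flipped: ~2% expected
    assert 0.01 < e < 0.035
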