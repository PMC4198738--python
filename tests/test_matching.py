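import itertools
import math

import numpy as np
import pytest
from scipy import stats

import snpauth as sa
NAN = np.nan


@pytest.mark.parametrize(
    "g1, g2, expected",
    [
        ([0, 1, 2] * 3 + [0], [0, 1, 2] * 3 + [0], (0, 10)),
        ([0, 1, 2, NAN], [0, 2, 2, 0], (1, 3)),
        ([0, 0, 0, 0, 0], [2, 2, 2, 2, 2], (5, 5)),
    ],
)
def test_difference_count(g1, g2, expected):
    assert sa.difference_count(g1, g2) == expected


def test_alignment_score_values():
    assert sa.alignment_score([0, 1, 2], [0, 1, 2]) == 1.0
    assert sa.alignment_score([0, 0], [2, 2]) == 0.0
    assert sa.alignment_score([0, 1, 2, 2], [0, 1, 2, 0]) == 0.75
    assert math.isnan(sa.alignment_score([NAN], [0]))


def test_alignment_score_identity_and_symmetry(rng):
    for _ in range(20):
        g = rng.choice([0.0, 1.0, 2.0, NAN], size=50, p=[0.4, 0.2, 0.35, 0.05])
        h = rng.choice([0.0, 1.0, 2.0, NAN], size=50, p=[0.4, 0.2, 0.35, 0.05])
        if np.isfinite(g).any():
            assert sa.alignment_score(g, g) == 1.0
        s1, s2 = sa.alignment_score(g, h), sa.alignment_score(h, g)
        assert (math.isnan(s1) and math.isnan(s2)) or s1 == s2


def test_pia_values_and_error_anchor():
    model = sa.ErrorModel(E=0.032)
    # ten differences put the misassignment probability at the 1e-15 scale
    assert sa.pia(10, model) == pytest.approx(1.1e-15, rel=0.05)
    assert sa.pia(0, model) == 1.0
    assert sa.pia(1, model) == 0.032


def test_pia_monotone_in_H_and_E():
    model = sa.ErrorModel(E=0.032)
    values = [sa.pia(h, model) for h in range(10)]
    assert all(a > b for a, b in zip(values, values[1:]))
    assert sa.pia(5, sa.ErrorModel(E=0.05)) > sa.pia(5, sa.ErrorModel(E=0.01))


def _match_fixture():
    """Query identical to A, 12 differences to B, 40 to C, over 500 markers."""
    rng = np.random.default_rng(0)
    n = 500
    a = rng.choice([0.0, 2.0], size=n)
    b = a.copy()
    b[rng.choice(n, 12, replace=False)] = 2.0 - b[rng.choice(n, 12, replace=False)]
    b = a.copy()
    idx = rng.choice(n, 12, replace=False)
    b[idx] = 2.0 - b[idx]
    c = a.copy()
    idx = rng.choice(n, 40, replace=False)
    c[idx] = 2.0 - c[idx]
    markers = {
        f"m{j}": sa.MarkerAnnotation(f"m{j}", "1", j + 1, ("A", "G")) for j in range(n)
    }
    samples = {
        "A": sa.SampleAnnotation("A", "reference", strain_label="A"),
        "B": sa.SampleAnnotation("B", "reference", strain_label="B"),
        "C": sa.SampleAnnotation("C", "reference", strain_label="C"),
        "Q": sa.SampleAnnotation("Q", "cell_line", strain_label="A"),
    }
    calls = np.vstack([a, b, c, a.copy()]).astype(np.float32)
    db = sa.Database(
        sa.GenotypeMatrix(["A", "B", "C", "Q"], list(markers), calls), markers, samples
    )
    assay = sa.AssayDefinition(list(markers), list(markers), 0.032)
    return db, assay


def test_best_match_constructed_fixture():
    db, assay = _match_fixture()
    res = sa.best_match("Q", db, assay)
    assert res.best_reference_id == "A"
    assert res.H_best == 0 and res.gap == 12
    assert res.alignment_score == 1.0
    assert res.PIA == pytest.approx(0.032**12, rel=1e-12)
    assert res.PIA == pytest.approx(1.15e-18, rel=0.01)
    assert res.verdict == "identity"


def test_best_match_verdict_thresholds():
    db, assay = _match_fixture()
    # exactly at the identity threshold: 500 * (1 - 0.96) = 20 differences
    g = db.genotypes
    q = g.row("A").copy()
    q[:20] = 2.0 - q[:20]
    g.calls[g.sample_position("Q")] = q
    res = sa.best_match("Q", db, assay)
    assert res.alignment_score == pytest.approx(0.96)
    assert res.verdict == "identity"
    q[20:40] = 2.0 - q[20:40]  # 40 differences -> score 0.92
    g.calls[g.sample_position("Q")] = q
    assert sa.best_match("Q", db, assay).verdict == "background_match"


def test_best_match_tie_is_ambiguous():
    db, assay = _match_fixture()
    g = db.genotypes
    # make B a copy of A: query (also A) ties between them at H = 0
    g.calls[g.sample_position("B")] = g.row("A")
    g.calls[g.sample_position("Q")] = g.row("A")
    res = sa.best_match("Q", db, assay)
    assert res.verdict == "ambiguous"
    assert set(res.tied_references) == {"A", "B"}


def test_f1_parent_pair_recovery():
    """Every in-silico F1 is recovered as its own best match: 100% at zero
    noise, at least 95% under 1% per-marker call error."""
    db = sa.make_reference_panel(sa.PanelSpec(n_strains=10, n_markers=800, seed=21))
    parents = list(db.genotypes.samples)
    panel = sa.generate_insilico_f1_panel(db, parents)
    f1_ids = panel.genotypes.samples[len(parents):]
    assay = sa.AssayDefinition(list(panel.genotypes.markers), list(panel.genotypes.markers), 0.032)

    def query_copies(call_error: float, seed: int) -> sa.Database:
        calls = sa.perturb_calls(
            panel.genotypes.calls, sa.NoiseSpec(call_error=call_error, no_call_rate=0.0, seed=seed)
        )
        copies = sa.Database(
            sa.GenotypeMatrix([s + "*" for s in panel.genotypes.samples],
                              panel.genotypes.markers, calls),
            panel.markers,
            {s + "*": sa.SampleAnnotation(s + "*", "cell_line")
             for s in panel.genotypes.samples},
        )
        return sa.merge_databases(panel, copies)

    clean = query_copies(0.0, 1)
    exact = sum(
        sa.best_match(f + "*", clean, assay).best_reference_id == f for f in f1_ids
    )
    assert exact == len(f1_ids)

    noisy = query_copies(0.01, 77)
    hits = sum(
        sa.best_match(f + "*", noisy, assay).best_reference_id == f for f in f1_ids
    )
    assert hits / len(f1_ids) >= 0.95


def _introgression_db(block_fraction=0.13, seed=3):
    """Cell line of strain A carrying one contiguous strain-B block."""
    db = sa.make_reference_panel(sa.PanelSpec(n_strains=6, n_markers=1200, seed=seed))
    order = db.markers_sorted()
    a = db.genotypes.row("S01").copy()
    b = db.genotypes.row("S02")
    n_block = int(block_fraction * len(order))
    block = [db.genotypes.marker_position(m) for m in order[100 : 100 + n_block]]
    a[block] = b[block]
    db2 = sa.add_cell_line(db, "S01", "CL_intro", reported_strain="S01")
    db2.genotypes.calls[db2.genotypes.sample_position("CL_intro")] = a
    return db2


def test_secondary_background_introgression_vs_contamination():
    db = _introgression_db()
    assay = sa.AssayDefinition(db.markers_sorted(), db.markers_sorted(), 0.032)
    primary = sa.best_match("CL_intro", db, assay)
    assert primary.best_reference_id == "S01"
    sec = sa.secondary_background("CL_intro", primary, db, assay, seed=5)
    assert sec.reference_id == "S02"
    assert sec.score_on_discordant > 0.9
    assert sec.interpretation == "introgression"

    # scattered 10% contamination-style discordance instead
    rng = np.random.default_rng(8)
    db2 = _introgression_db(block_fraction=0.0)
    g = db2.genotypes
    a = g.row("S01").copy()
    b = g.row("S02")
    scatter = rng.choice(len(a), size=int(0.1 * len(a)), replace=False)
    a[scatter] = b[scatter]
    g.calls[g.sample_position("CL_intro")] = a
    primary2 = sa.best_match("CL_intro", db2, assay)
    sec2 = sa.secondary_background("CL_intro", primary2, db2, assay, seed=5)
    assert sec2.interpretation == "contamination_suspect"


def test_secondary_none_for_perfect_match():
    db, assay = _match_fixture()
    res = sa.best_match("Q", db, assay)
    sec = sa.secondary_background("Q", res, db, assay)
    assert sec.interpretation == "none" and sec.reference_id is None


def _uniform_positions(n, seed=0):
    rng = np.random.default_rng(seed)
    return {"1": sorted(rng.choice(10**8, size=n, replace=False).tolist())}


def test_clustering_test_detects_contiguous_block():
    all_pos = _uniform_positions(1000)
    disc = {"1": all_pos["1"][200:240]}  # 40 contiguous markers
    p = sa.discordance_clustering_test(disc, all_pos, n_perm=999, seed=1)
    assert p <= 0.01


def test_clustering_test_two_adjacent_matches_enumeration():
    """With 2 discordant of 1,000 markers the null is exactly enumerable:
    P(gap <= 1) = 999 / C(1000, 2)."""
    all_pos = _uniform_positions(1000, seed=2)
    disc = {"1": all_pos["1"][500:502]}
    exact = 999 / math.comb(1000, 2)  # ~0.002
    n_perm = 4999
    p = sa.discordance_clustering_test(disc, all_pos, n_perm=n_perm, seed=3)
    # permutation p estimates (1 + n_perm * exact) / (n_perm + 1)
    expected = (1 + n_perm * exact) / (n_perm + 1)
    se = math.sqrt(exact * (1 - exact) / n_perm)
    assert abs(p - expected) < 4 * se + 1e-9


def test_clustering_pvalues_uniform_under_null():
    """p-values over random discordance placements are uniform (KS check)."""
    all_pos = _uniform_positions(300, seed=4)
    rng = np.random.default_rng(11)
    pvals = []
    for i in range(500):
        picks = np.sort(rng.choice(300, size=10, replace=False))
        disc = {"1": [all_pos["1"][j] for j in picks]}
        pvals.append(
            sa.discordance_clustering_test(disc, all_pos, n_perm=199, seed=1000 + i)
        )
    ks = stats.kstest(pvals, "uniform")
    assert ks.pvalue > 0.01
    assert np.median(pvals) > 0.2


def test_pairwise_difference_matrix_consistency(small_panel):
    calls = small_panel.genotypes.calls[:10]
    H = sa.pairwise_difference_matrix(calls)
    assert H.shape == (10, 10)
    assert np.array_equal(H, H.T) and (np.diag(H) == 0).all()
    for i, j in itertools.combinations(range(10), 2):
        assert H[i, j] == sa.difference_count(calls[i], calls[j])[0]
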