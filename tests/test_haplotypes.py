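"""EHH / iHH / iHS against brute-force pairwise oracles and closed forms."""

import itertools

import numpy as np
import pytest

from clinesel.haplotypes import (
    ANCESTRAL,
    DERIVED,
    IhsRecord,
    ehh,
    ehh_decay_distance,
    ihs_percentile,
    ihs_scan,
    integrated_ehh,
    standardize_ihs,
    unstandardized_ihs,
)
from conftest import make_panel

# ---------------------------------------------------------------- oracles


def ehh_oracle(alleles, core, allele, direction, x):
    """Probability two random carrier chromosomes are identical from the core
    out to site x, by exhaustive pairwise comparison."""
    carriers = [i for i in range(alleles.shape[0]) if alleles[i, core] == allele]
    lo, hi = (x, core) if direction < 0 else (core, x)
    span = slice(lo, hi + 1)
    same = sum(
        1
        for i, j in itertools.combinations(carriers, 2)
        if np.array_equal(alleles[i, span], alleles[j, span])
    )
    n = len(carriers)
    return same / (n * (n - 1) / 2)


def ihh_oracle(panel, core, allele, threshold=0.05):
    """Trapezoid integral of oracle EHH values, truncated at the last site
    with EHH >= threshold in each direction."""
    total = 0.0
    for step in (-1, +1):
        xs, vals = [core], [1.0]
        j = core + step
        while 0 <= j < panel.n_sites:
            v = ehh_oracle(panel.alleles, core, allele, step, j)
            xs.append(j)
            vals.append(v)
            if v < threshold:
                break
            j += step
        vals = np.array(vals)
        dist = np.abs(panel.positions_cm[xs] - panel.positions_cm[core])
        keep = np.flatnonzero(vals >= threshold)
        if keep.size >= 2:
            last = keep[-1]
            total += np.trapezoid(vals[: last + 1], dist[: last + 1])
    return total


# ---------------------------------------------------------------- EHH


def test_ehh_starts_at_one_and_is_nonincreasing(random_panel):
    for allele in (ANCESTRAL, DERIVED):
        curve = ehh(random_panel, 6, allele)
        for d in ("left", "right"):
            vals = curve.direction(d)["ehh"]
            assert vals[0] == 1.0
            assert np.all(np.diff(vals) <= 1e-12)


def test_ehh_four_carriers_two_groups_of_two():
    # four derived carriers split into two identical pairs one site out:
    # EHH = (C(2,2) + C(2,2)) / C(4,2) = 2/6 = 1/3
    alleles = [
        [1, 0],
        [1, 0],
        [1, 1],
        [1, 1],
        [0, 0],
        [0, 1],
    ]
    curve = ehh(make_panel(alleles), 0, DERIVED)
    assert curve.right["ehh"][1] == pytest.approx(1 / 3)


def test_ehh_all_carriers_identical_stays_one():
    alleles = [[1, 0, 1, 1]] * 4 + [[0, 1, 0, 0], [0, 0, 1, 0]]
    curve = ehh(make_panel(alleles), 0, DERIVED)
    assert np.all(curve.right["ehh"] == 1.0)


def test_ehh_matches_exhaustive_oracle(random_panel):
    """Full oracle equivalence on a 16 x 12 panel, every core/allele/site."""
    for core in range(random_panel.n_sites):
        for allele in (ANCESTRAL, DERIVED):
            if (random_panel.alleles[:, core] == allele).sum() < 2:
                continue
            curve = ehh(random_panel, core, allele)
            for step, d in ((-1, "left"), (1, "right")):
                sites = curve.direction(d)["sites"]
                vals = curve.direction(d)["ehh"]
                for x, v in zip(sites[1:], vals[1:]):
                    assert v == pytest.approx(
                        ehh_oracle(random_panel.alleles, core, allele, step, x), abs=1e-12
                    )


def test_ehh_invariant_to_row_permutation_and_noncore_relabel(random_panel, rng):
    core = 5
    base = ehh(random_panel, core, DERIVED)
    perm = rng.permutation(random_panel.n_haplotypes)
    p2 = make_panel(random_panel.alleles[perm])
    flipped = random_panel.alleles.copy()
    flipped[:, [2, 8]] = 1 - flipped[:, [2, 8]]  # relabel ref/alt at non-core sites
    p3 = make_panel(flipped)
    for other in (p2, p3):
        c2 = ehh(other, core, DERIVED)
        for d in ("left", "right"):
            np.testing.assert_allclose(c2.direction(d)["ehh"], base.direction(d)["ehh"])


def test_ehh_too_few_carriers_raises():
    alleles = [[1, 0], [0, 0], [0, 1]]
    with pytest.raises(ValueError, match="carry"):
        ehh(make_panel(alleles), 0, DERIVED)


# ---------------------------------------------------------------- decay distance


def test_decay_distance_last_site_at_or_above_threshold():
    # EHH [1, 0.6, 0.04] at 0/10/20 kb -> decay distance 10 kb, not censored
    alleles = np.zeros((10, 3), dtype=np.int8)
    alleles[:5, 0] = 1
    curve = ehh(make_panel(alleles, bp_spacing=10_000), 0, DERIVED)
    curve.right.update(ehh=np.array([1.0, 0.6, 0.04]))
    d = ehh_decay_distance(curve)
    assert d["right"] == (10_000, False)


def test_decay_distance_censored_at_panel_edge():
    alleles = [[1, 1, 1]] * 3 + [[0, 0, 1], [0, 1, 0], [0, 1, 1]]
    curve = ehh(make_panel(alleles, bp_spacing=10_000), 0, DERIVED)
    dist, censored = ehh_decay_distance(curve)["right"]
    assert censored and dist == 20_000


# ---------------------------------------------------------------- iHH


def test_ihh_trapezoid_by_hand():
    # one direction: EHH [1, 0.5] over 1 cM then below threshold -> 0.75 cM
    alleles = np.array(
        [[1, 1, 0], [1, 1, 0], [1, 0, 0], [1, 0, 1], [0, 1, 1], [0, 0, 1]], dtype=np.int8
    )
    # derived carriers: rows 0-3; at site 1 they split 2/2 -> EHH = 1/3 < .5...
    # use explicit curve arithmetic instead: integrate a hand-made curve
    panel = make_panel(alleles, bp_spacing=1_000_000)  # 1 cM between sites
    curve = ehh(panel, 0, DERIVED)
    curve.left.update(ehh=np.array([1.0]), distance_cm=np.array([0.0]))
    curve.right.update(
        ehh=np.array([1.0, 0.5, 0.01]), distance_cm=np.array([0.0, 1.0, 2.0])
    )
    assert integrated_ehh(curve) == pytest.approx(0.75)


def test_ihh_rectangle_and_two_direction_additivity():
    alleles = [[1, 1, 1], [1, 1, 1], [1, 1, 1], [0, 0, 1], [1, 0, 0], [0, 0, 0]]
    panel = make_panel(alleles, bp_spacing=1_000_000)
    curve = ehh(panel, 1, DERIVED)  # EHH identically 1 both sides, 1 cM each
    assert integrated_ehh(curve) == pytest.approx(2.0)


def test_ihh_matches_oracle(random_panel):
    for core in range(2, 10):
        for allele in (ANCESTRAL, DERIVED):
            if (random_panel.alleles[:, core] == allele).sum() < 2:
                continue
            curve = ehh(random_panel, core, allele, stop_below=0.05)
            assert integrated_ehh(curve) == pytest.approx(
                ihh_oracle(random_panel, core, allele), abs=1e-12
            )


# ---------------------------------------------------------------- iHS


def test_ihs_zero_under_mirror_symmetry():
    # derived and ancestral carriers with mirror-image structure
    block = np.array([[0, 0, 0], [0, 1, 0], [1, 0, 1], [1, 1, 1]], dtype=np.int8)
    alleles = np.column_stack(
        [block[:, :1], np.array([[1], [1], [0], [0]]), block[:, 1:]]
    )
    alleles = np.vstack([alleles, 1 - alleles])  # each class sees the same partitions
    panel = make_panel(alleles)
    rec = unstandardized_ihs(panel, 1)
    assert rec.ihs_unstd == pytest.approx(0.0, abs=1e-12)


def test_ihs_negative_when_derived_haplotypes_longer():
    rng = np.random.default_rng(5)
    n_sites = 11
    derived = np.tile(np.r_[1, rng.integers(0, 2, n_sites - 1)], (8, 1))
    ancestral = np.column_stack(
        [np.zeros(8, int), rng.integers(0, 2, (8, n_sites - 1))]
    )
    panel = make_panel(np.vstack([derived, ancestral])[:, :])
    # put the core in the middle so both directions contribute
    order = np.r_[5, np.delete(np.arange(n_sites), 5)]
    rec = unstandardized_ihs(make_panel(np.vstack([derived, ancestral])), 0)
    assert rec.ihs_unstd < 0


def test_ihs_matches_oracle_and_antisymmetry(random_panel):
    for core in (3, 6, 9):
        rec = unstandardized_ihs(random_panel, core)
        ihh_a = ihh_oracle(random_panel, core, ANCESTRAL)
        ihh_d = ihh_oracle(random_panel, core, DERIVED)
        if ihh_a > 0 and ihh_d > 0:
            assert rec.ihs_unstd == pytest.approx(np.log(ihh_a / ihh_d), abs=1e-12)
        # swapping ancestral/derived labels negates iHS exactly
        swapped = make_panel(1 - random_panel.alleles)
        rec_sw = unstandardized_ihs(swapped, core)
        assert rec_sw.ihs_unstd == pytest.approx(-rec.ihs_unstd, abs=1e-12)


def test_ihs_maf_filter_rejects_rare_sites():
    alleles = np.zeros((40, 5), dtype=np.int8)
    alleles[0, 2] = 1  # MAF 0.025
    with pytest.raises(ValueError, match="MAF"):
        unstandardized_ihs(make_panel(alleles), 2)


# ---------------------------------------------------------------- standardization


def _recs(values, freqs):
    return [
        IhsRecord(site=i, site_id=f"s{i}", derived_freq=f, ihh_ancestral=1.0,
                  ihh_derived=1.0, ihs_unstd=v)
        for i, (v, f) in enumerate(zip(values, freqs))
    ]


def test_standardize_single_bin_values():
    recs = standardize_ihs(_recs([1.0, 2.0, 3.0], [0.5, 0.5, 0.5]), n_bins=1)
    assert [r.ihs_std for r in recs] == pytest.approx([-1.0, 0.0, 1.0])


def test_standardize_degenerate_bin_missing():
    recs = standardize_ihs(_recs([2.0, 2.0, 2.0], [0.5, 0.5, 0.5]), n_bins=1)
    assert all(r.ihs_std is None for r in recs)


def test_standardize_idempotent():
    rng = np.random.default_rng(0)
    vals = rng.normal(size=200)
    freqs = rng.uniform(0.05, 0.95, 200)
    recs = standardize_ihs(_recs(vals, freqs), n_bins=5)
    once = [r.ihs_std for r in recs]
    again = standardize_ihs(
        _recs([r.ihs_std for r in recs], freqs), n_bins=5
    )
    np.testing.assert_allclose([r.ihs_std for r in again], once, atol=1e-10)


def test_standardize_empty_rejected():
    with pytest.raises(ValueError):
        standardize_ihs([])


# ---------------------------------------------------------------- percentile


def test_percentile_by_definition():
    background = np.arange(1, 101) / 10.0  # magnitudes 0.1 .. 10.0
    assert ihs_percentile(-9.65, background) == pytest.approx(96.0)
    assert ihs_percentile(0.05, background) == 0.0
    with pytest.raises(ValueError):
        ihs_percentile(1.0, np.array([]))
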