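"""Windowed matching, the Φ recursion and dCn."""

import numpy as np
import pytest

from phosloc.configurations import (
    apply_coincidence_rules,
    build_ladders,
    enumerate_configurations,
    flag_site_determining,
    parse_label,
)
from phosloc.io import Spectrum
from phosloc.masses import ModifiedPeptide, STANDARD_AA, fragment_ladder
from phosloc.scoring import (
    MatchParameters,
    delta_cn,
    max_peak_in_window,
    phi_score,
    rank_configurations,
    top_is_tied,
    zeta_threshold,
)


def _spectrum(peaks, fragmentation="HCD", charge=2):
    mz, intensity = zip(*peaks) if peaks else ((), ())
    return Spectrum(
        scan_id="s",
        precursor_neutral_mass=1000.0,
        precursor_charge=charge,
        mz=np.array(mz, dtype=float),
        intensity=np.array(intensity, dtype=float),
        fragmentation=fragmentation,
    )


def _targets(label, charge=2, delta=0.05, sd_only=True):
    cset = enumerate_configurations(parse_label(label, precursor_charge=charge))
    build_ladders(cset)
    flag_site_determining(cset, tolerance=delta)
    apply_coincidence_rules(cset, tolerance=delta)
    out = []
    for targets in cset.scoring_targets:
        out.append([t for t in targets if t.site_determining or not sd_only])
    return cset, out


# ---------------------------------------------------------------- window


@pytest.mark.parametrize(
    "peaks,target,expected",
    [
        ([(100.00, 500.0)], 100.02, (500.0, 100.00)),  # 0.02 <= delta/2
        ([(100.00, 500.0), (100.02, 800.0)], 100.00, (800.0, 100.02)),  # max wins
        ([(100.00, 500.0)], 100.04, None),  # 0.04 > delta/2
    ],
)
def test_max_peak_in_window(peaks, target, expected):
    assert max_peak_in_window(_spectrum(peaks), target, delta=0.05) == expected


# ---------------------------------------------------------------- zeta


def test_zeta_resolves_by_fragmentation():
    peaks = [(100.0, 1000.0), (200.0, 10.0)]
    params = MatchParameters()
    assert zeta_threshold(_spectrum(peaks, "HCD"), params) == pytest.approx(30.0)
    assert zeta_threshold(_spectrum(peaks, "CID"), params) == pytest.approx(50.0)


def test_zeta_override_and_empty_spectrum():
    peaks = [(100.0, 1000.0)]
    assert zeta_threshold(_spectrum(peaks), MatchParameters(min_rel_intensity=0.0)) == 0.0
    assert zeta_threshold(_spectrum([]), MatchParameters()) == float("inf")


# ---------------------------------------------------------------- phi


def test_phi_sums_matched_intensities():
    """Non-negative intensities make inclusion always optimal."""
    cset, targets = _targets("PQS*VLTK")
    t1, t2 = targets[0][0], targets[0][1]
    spectrum = _spectrum([(t1.mz, 500.0), (t2.mz, 300.0)])
    scored = phi_score(spectrum, [t1, t2], MatchParameters(min_rel_intensity=0.0))
    assert scored.phi == pytest.approx(800.0)
    assert len(scored.matched) == 2


def test_phi_rejects_sub_zeta_peaks():
    cset, targets = _targets("PQS*VLTK")
    t1, t2 = targets[0][0], targets[0][1]
    # tallest peak 1000 -> HCD zeta 30; the 20-intensity match is rejected
    spectrum = _spectrum([(t1.mz, 500.0), (t2.mz, 20.0), (900.0, 1000.0)])
    scored = phi_score(spectrum, [t1, t2], MatchParameters())
    assert scored.phi == pytest.approx(500.0)


def test_phi_empty_inputs_score_zero():
    cset, targets = _targets("PQS*VLTK")
    params = MatchParameters()
    assert phi_score(_spectrum([]), targets[0], params).phi == 0.0
    assert phi_score(_spectrum([(100.0, 5.0)]), [], params).phi == 0.0


def test_one_observed_peak_contributes_once():
    """Two targets in range of one peak: the first ladder-order claimant wins."""
    cset, targets = _targets("PQS*VLTK")
    t1, t2 = targets[0][0], targets[0][1]
    mid = (t1.mz + t2.mz) / 2
    width = abs(t2.mz - t1.mz) * 2 + 0.1
    spectrum = _spectrum([(mid, 700.0)])
    scored = phi_score(
        spectrum, [t1, t2], MatchParameters(window_delta=width, min_rel_intensity=0.0)
    )
    assert scored.phi == pytest.approx(700.0)
    assert len(scored.matched) == 1
    assert scored.matched[0][0] is t1


def brute_force_phi(spectrum, targets, delta, zeta):
    """Independent oracle: thresholded summation with linear window scans."""
    claimed = set()
    total = 0.0
    for target in targets:
        best_idx, best_int = None, None
        for idx, (mz, inten) in enumerate(zip(spectrum.mz, spectrum.intensity)):
            if idx in claimed or inten < zeta:
                continue
            if target.mz - delta / 2 <= mz <= target.mz + delta / 2:
                if best_int is None or inten > best_int:
                    best_idx, best_int = idx, inten
        if best_idx is not None:
            claimed.add(best_idx)
            total += best_int
    return total


def _random_instance(rng):
    letters = np.array(list(STANDARD_AA))
    while True:
        seq = "".join(rng.choice(letters, size=rng.integers(6, 13)))
        sites = [i + 1 for i, aa in enumerate(seq) if aa in "STY"]
        if len(sites) >= 2:
            break
    p = int(rng.integers(1, min(len(sites), 2) + 1))
    hit = ModifiedPeptide(
        sequence=seq, precursor_charge=2, phospho_positions=tuple(sites[:p])
    )
    cset = enumerate_configurations(hit)
    build_ladders(cset)
    flag_site_determining(cset)
    apply_coincidence_rules(cset)
    theo = np.array([ion.mz for ion in fragment_ladder(hit)])
    keep = rng.random(theo.size) < 0.5
    mz = np.concatenate(
        [
            theo[keep] + rng.normal(0, 0.01, int(keep.sum())),
            rng.uniform(100, 1500, 40),
        ]
    )
    intensity = rng.uniform(1.0, 1000.0, mz.size)
    spectrum = _spectrum(list(zip(mz.tolist(), intensity.tolist())))
    return cset, spectrum


def test_dp_equals_bruteforce_summation(rng):
    """The Φ recursion reduces exactly to thresholded summation."""
    params = MatchParameters()
    for _ in range(200):
        cset, spectrum = _random_instance(rng)
        zeta = zeta_threshold(spectrum, params)
        for targets in cset.scoring_targets:
            sd = [t for t in targets if t.site_determining]
            scored = phi_score(spectrum, sd, params, zeta=zeta)
            assert scored.phi == brute_force_phi(spectrum, sd, params.window_delta, zeta)


def test_phi_monotone_in_delta_and_zeta(rng):
    """Widening the window or lowering the floor never decreases Φ."""
    for _ in range(30):
        cset, spectrum = _random_instance(rng)
        sd = [t for t in cset.scoring_targets[0] if t.site_determining]
        phis = [
            phi_score(spectrum, sd, MatchParameters(window_delta=d, min_rel_intensity=z)).phi
            for d, z in [(0.01, 0.5), (0.05, 0.5), (0.05, 0.03), (0.2, 0.0)]
        ]
        assert phis == sorted(phis)


def test_phi_scale_equivariance(rng):
    """Scaling all intensities by c scales Φ by c; ranking and dCn unmoved."""
    cset, spectrum = _random_instance(rng)
    params = MatchParameters()
    ranked = rank_configurations(cset, spectrum, params)
    scaled = Spectrum(
        scan_id="s",
        precursor_neutral_mass=spectrum.precursor_neutral_mass,
        precursor_charge=spectrum.precursor_charge,
        mz=spectrum.mz,
        intensity=spectrum.intensity * 7.5,
        fragmentation=spectrum.fragmentation,
    )
    ranked_scaled = rank_configurations(cset, scaled, params)
    assert [s.label for s in ranked] == [s.label for s in ranked_scaled]
    for a, b in zip(ranked, ranked_scaled):
        assert b.phi == pytest.approx(7.5 * a.phi, rel=1e-12)
    assert delta_cn(ranked_scaled) == pytest.approx(delta_cn(ranked), abs=1e-12)


def test_evaluation_work_is_bounded_linearly():
    """Targets evaluated per configuration never exceed (L-1) * 12 * charge."""
    cset, targets = _targets("ADS*STFEAK", charge=2)
    spectrum = _spectrum([(300.0, 10.0)])
    ranked = rank_configurations(cset, spectrum, MatchParameters())
    bound = (len("ADSSTFEAK") - 1) * 12 * 2
    assert all(s.n_evaluations <= bound for s in ranked)


# ---------------------------------------------------------------- ranking / dCn


def test_ranking_descending_and_tie_flag():
    cset, targets = _targets("PQS*VLTK")
    sd0 = [t for t in cset.scoring_targets[0] if t.site_determining]
    spectrum = _spectrum([(sd0[0].mz, 900.0)])
    ranked = rank_configurations(cset, spectrum, MatchParameters(min_rel_intensity=0.0))
    assert ranked[0].label == "PQS*VLTK" and ranked[0].phi == pytest.approx(900.0)
    assert ranked[1].phi == 0.0
    assert not top_is_tied(ranked)

    empty = rank_configurations(cset, _spectrum([]), MatchParameters())
    assert [s.label for s in empty] == ["PQS*VLTK", "PQSVLT*K"]  # label order on tie
    assert top_is_tied(empty)


class _Fake:
    def __init__(self, phi, label="x"):
        self.phi = phi
        self.label = label


@pytest.mark.parametrize(
    "phis,expected",
    [((100.0, 0.0), 1.0), ((50.0, 50.0), 0.0), ((200.0, 150.0), 0.25), ((0.0, 0.0), 0.0)],
)
def test_delta_cn_arithmetic(phis, expected):
    ranked = [_Fake(p) for p in phis]
    assert delta_cn(ranked) == pytest.approx(expected)


def test_delta_cn_singleton_is_confident():
    assert delta_cn([_Fake(0.0)]) == 1.0
    with pytest.raises(ValueError):
        delta_cn([])
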