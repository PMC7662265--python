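"""Secondary shifts, segment detection and two-state helix populations."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pephelix.chemshift import (
    DeltaProfile,
    HelixSegment,
    PopulationEstimate,
    ShiftTable,
    ShiftTableError,
    combine_populations,
    detect_helical_segments,
    helix_population,
    read_shift_table,
    secondary_shifts,
    segment_average,
    write_shift_csv,
    write_star_shift_loop,
)
from pephelix.sequences import parse_peptide
from pephelix.synthetic import HelixProfile, SimulationSpec, simulate_shift_table


def brute_force_segments(values, rc_band=0.05, min_length=3):
    """Independent oracle: all maximal intervals of consecutive present
    residues, every one below -rc_band, of sufficient length."""
    def qualifies(a, b):
        return all(n in values and values[n] < -rc_band for n in range(a, b + 1))

    nums = sorted(values)
    if not nums:
        return []
    candidates = [
        (a, b)
        for a in nums
        for b in nums
        if b - a + 1 >= min_length and qualifies(a, b)
    ]
    maximal = [
        (a, b)
        for (a, b) in candidates
        if not qualifies(a - 1, b) and not qualifies(a, b + 1)
    ]
    return [HelixSegment(a, b) for a, b in sorted(maximal)]


class TestShiftTableIO:
    def make_table(self, cb1):
        shifts = {
            (391, "HA"): 4.30, (391, "CA"): 61.9,
            (392, "HA"): 4.05, (392, "CA"): 62.5, (392, "HN"): 8.10,
            (393, "HA"): 4.70, (393, "CA"): 53.2,
        }
        return ShiftTable(cb1, "TFE", shifts)

    def test_csv_round_trip(self, tmp_path, cb1):
        table = self.make_table(cb1)
        path = tmp_path / "shifts.csv"
        write_shift_csv(table, path)
        back = read_shift_table(path, cb1, "TFE")
        assert set(back.shifts) == set(table.shifts)
        for key in table.shifts:
            assert back.shifts[key] == pytest.approx(table.shifts[key], abs=1e-4)

    def test_nmrstar_equals_csv(self, tmp_path, cb1):
        table = self.make_table(cb1)
        csv_path, star_path = tmp_path / "s.csv", tmp_path / "s.str"
        write_shift_csv(table, csv_path)
        write_star_shift_loop(table, star_path)
        from_csv = read_shift_table(csv_path, cb1, "TFE")
        from_star = read_shift_table(star_path, cb1, "TFE", format="nmrstar")
        assert set(from_star.shifts) == set(from_csv.shifts)
        for key in from_csv.shifts:
            assert from_star.shifts[key] == pytest.approx(from_csv.shifts[key], abs=1e-4)

    def test_residue_outside_peptide_rejected(self, tmp_path, cb1):
        path = tmp_path / "bad.csv"
        path.write_text(
            "residue_number,residue_code,nucleus,shift_ppm\n999,A,HA,4.3\n"
        )
        with pytest.raises(ShiftTableError, match="999"):
            read_shift_table(path, cb1)

    def test_duplicate_entry_rejected(self, tmp_path, cb1):
        path = tmp_path / "dup.csv"
        path.write_text(
            "residue_number,residue_code,nucleus,shift_ppm\n"
            "391,T,HA,4.3\n391,T,HA,4.4\n"
        )
        with pytest.raises(ShiftTableError, match="duplicate"):
            read_shift_table(path, cb1)

    def test_proline_hn_rejected(self, cb1):
        with pytest.raises(ShiftTableError, match="Pro"):
            ShiftTable(cb1, "H2O", {(394, "HN"): 8.2})

    def test_shift_range_validated(self, cb1):
        with pytest.raises(ShiftTableError):
            ShiftTable(cb1, "H2O", {(391, "HA"): 50.0})


class TestSecondaryShifts:
    def test_identity_gives_zero_profile(self, cb1, rc):
        shifts = {
            (num, nuc): rc.shift(cb1.residue(num).code, nuc)
            for num in cb1.residue_numbers
            for nuc in ("HA", "CA")
        }
        table = ShiftTable(cb1, "H2O", shifts)
        for nuc in ("HA", "CA"):
            profile = secondary_shifts(table, rc, nuc)
            assert all(v == pytest.approx(0.0) for v in profile.values.values())

    def test_exact_inversion(self, cb1, rc):
        table = simulate_shift_table(
            cb1, HelixProfile.flat(0.6, 19), rc, SimulationSpec(seed=11)
        )
        for nuc in ("HA", "CA"):
            profile = secondary_shifts(table, rc, nuc)
            for num, delta in profile.values.items():
                rc_val = rc.shift(cb1.residue(num).code, nuc)
                assert rc_val + delta == pytest.approx(table.get(num, nuc), abs=1e-12)

    def test_full_helix_limit_recovered(self, cb1, rc):
        table = simulate_shift_table(
            cb1,
            HelixProfile.flat(1.0, 19),
            rc,
            SimulationSpec(seed=0, noise_h_ppm=0.0, noise_c_ppm=0.0),
        )
        ha = secondary_shifts(table, rc, "HA")
        ca = secondary_shifts(table, rc, "CA")
        assert all(v == pytest.approx(-0.39) for v in ha.values.values())
        assert all(v == pytest.approx(3.1) for v in ca.values.values())

    def test_missing_residue_absent(self, cb1, rc):
        table = ShiftTable(cb1, "H2O", {(391, "HA"): 4.3, (393, "HA"): 4.7})
        profile = secondary_shifts(table, rc, "HA")
        assert 392 not in profile and set(profile.residues()) == {391, 393}

    def test_hn_unsupported(self, cb1, rc):
        table = ShiftTable(cb1, "H2O", {(391, "HA"): 4.3})
        with pytest.raises(ShiftTableError):
            secondary_shifts(table, rc, "HN")


class TestSegmentDetection:
    def test_hinged_profile_decomposition(self):
        # negative dHA over 394-402 and 404-408, positive at the 403 hinge
        values = {n: -0.2 for n in range(394, 403)}
        values[403] = 0.1
        values.update({n: -0.15 for n in range(404, 409)})
        values[391] = 0.02
        profile = DeltaProfile("HA", values)
        assert detect_helical_segments(profile) == [
            HelixSegment(394, 402),
            HelixSegment(404, 408),
        ]

    def test_all_zero_profile(self):
        profile = DeltaProfile("HA", {n: 0.0 for n in range(1, 20)})
        assert detect_helical_segments(profile) == []

    def test_alternating_profile_no_run(self):
        values = {n: (-0.2 if n % 2 else 0.2) for n in range(1, 20)}
        assert detect_helical_segments(DeltaProfile("HA", values)) == []

    def test_empty_profile(self):
        assert detect_helical_segments(DeltaProfile("HA", {})) == []

    def test_band_boundary_is_exclusive(self):
        # exactly -rc_band does not qualify as helical
        values = {n: -0.05 for n in range(1, 10)}
        assert detect_helical_segments(DeltaProfile("HA", values)) == []

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        st.dictionaries(
            st.integers(min_value=1, max_value=25),
            st.floats(min_value=-0.5, max_value=0.5, allow_nan=False),
            max_size=25,
        )
    )
    def test_matches_brute_force_oracle(self, values):
        profile = DeltaProfile("HA", values)
        assert detect_helical_segments(profile) == brute_force_segments(values)


class TestSegmentAverage:
    def test_hand_mean(self):
        profile = DeltaProfile("HA", {1: -0.2, 2: -0.3, 3: -0.1})
        assert segment_average(profile, HelixSegment(1, 3)) == pytest.approx(-0.2)

    def test_missing_residue_excluded(self):
        profile = DeltaProfile("HA", {1: -0.2, 3: -0.1})
        assert segment_average(profile, HelixSegment(1, 3)) == pytest.approx(-0.15)

    def test_constant_profile_idempotent(self):
        profile = DeltaProfile("CA", {n: 1.7 for n in range(5, 15)})
        assert segment_average(profile, HelixSegment(6, 9)) == pytest.approx(1.7)

    def test_empty_segment_rejected(self):
        profile = DeltaProfile("HA", {1: -0.2})
        with pytest.raises(ShiftTableError):
            segment_average(profile, HelixSegment(5, 9))


class TestHelixPopulation:
    # (avg ppm, nucleus, expected integer %) from the measured segment averages
    MEASURED = [
        (-0.24, "HA", 62),
        (2.50, "CA", 81),
        (1.22, "CA", 39),
        (-0.12, "HA", 31),
        (0.0, "HA", 0),
    ]

    @pytest.mark.parametrize("avg, nucleus, expected", MEASURED)
    def test_measured_averages(self, avg, nucleus, expected):
        assert helix_population(avg, nucleus).percent_rounded == expected

    def test_propagated_errors(self):
        assert helix_population(-0.2, "HA").error_percent == pytest.approx(100 * 0.01 / 0.39)
        assert helix_population(2.0, "CA").error_percent == pytest.approx(100 * 0.1 / 3.1)

    def test_monotonic_in_delta(self):
        percents = [helix_population(d, "HA").percent for d in np.linspace(0, -0.39, 9)]
        assert all(a < b for a, b in zip(percents, percents[1:]))

    def test_out_of_range_flagged(self):
        est = helix_population(-0.5, "HA")
        assert est.percent > 100 and not est.in_range

    def test_unsupported_nucleus(self):
        with pytest.raises(ShiftTableError):
            helix_population(0.1, "HN")


class TestCombinePopulations:
    @staticmethod
    def estimate(percent, nucleus, segment=HelixSegment(394, 402)):
        return PopulationEstimate(percent, 3.0, nucleus, segment)

    @pytest.mark.parametrize(
        "p_ha, p_ca, expected, expected_sd",
        [(37, 49, 43, 6), (22, 16, 19, 3), (50, 50, 50, 0)],
    )
    def test_mean_and_spread(self, p_ha, p_ca, expected, expected_sd):
        combined = combine_populations(
            self.estimate(p_ha, "HA"), self.estimate(p_ca, "CA")
        )
        assert combined.percent == expected
        assert combined.error_percent == expected_sd
        assert combined.nucleus == "combined"

    def test_segment_mismatch_rejected(self):
        with pytest.raises(ShiftTableError):
            combine_populations(
                self.estimate(30, "HA", HelixSegment(394, 402)),
                self.estimate(40, "CA", HelixSegment(404, 408)),
            )


class TestParameterRecovery:
    """Two-state simulate -> analyze round trip at the stated noise levels."""

    @pytest.mark.parametrize("f", [0.2, 0.5, 0.8])
    def test_flat_profile_recovery(self, cb1, rc, f):
        segment = HelixSegment(cb1.start_number, cb1.end_number)
        hits = {"HA": 0, "CA": 0}
        n_rep = 200
        for rep in range(n_rep):
            spec = SimulationSpec(seed=1000 * int(f * 10) + rep)
            table = simulate_shift_table(cb1, HelixProfile.flat(f, len(cb1)), rc, spec)
            for nuc, tol in (("HA", 3.0), ("CA", 7.0)):
                profile = secondary_shifts(table, rc, nuc)
                est = helix_population(segment_average(profile, segment), nuc)
                if abs(est.percent - 100.0 * f) <= tol:
                    hits[nuc] += 1
        assert hits["HA"] >= 0.95 * n_rep
        assert hits["CA"] >= 0.95 * n_rep
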