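"""Three-criterion SAAV assignment and open-search table normalization."""

import numpy as np
import pandas as pd
import pytest

from conftest import brute_force_assign
from saavbench.catalog import compute_saav_mass_shift
from saavbench.masses import STANDARD_AA
from saavbench.openparse import (
    REJECT_NO_PAIR,
    REJECT_ORIGIN,
    accepted_candidates,
    assign_saav,
    assign_saav_table,
    filter_localized_psms,
    normalize_psm_table,
    theoretical_saav_entries,
)


class TestAssignSaav:
    def test_ch2_tie_family_resolved_by_origin(self):
        """+14.0157 matches five isobaric pairs; the V origin selects V→X."""
        res = assign_saav("AKHPMDTEVTK", 14.0157, 9)
        assert res.accepted
        assert (res.from_aa, res.to_aa) == ("V", "X")
        assert res.variant_peptide == "AKHPMDTEXTK"
        assert res.delta_delta_mass < 0.001

    def test_origin_mismatch_blocks_nearer_tie_family(self):
        """The +CH2 family's origins exclude M, so a +14.0157 shift at an M
        site is rejected even though farther M-origin pairs exist."""
        res = assign_saav("AKHPMDTEVTK", 14.0157, 5)
        assert not res.accepted
        assert res.reject_reason == REJECT_ORIGIN

    def test_shift_far_from_any_pair_rejected(self):
        res = assign_saav("AAANAAK", 0.50, 4)
        assert not res.accepted
        assert res.reject_reason == REJECT_NO_PAIR

    def test_exact_match_accepted(self):
        res = assign_saav("AAATAAK", -3.99492, 4)
        assert res.accepted
        assert (res.from_aa, res.to_aa) == ("T", "P")

    def test_site_outside_peptide_is_an_error(self):
        with pytest.raises(ValueError):
            assign_saav("AAATAAK", 1.0, 9)

    def test_missing_delta_mass_is_an_error(self):
        with pytest.raises(ValueError):
            assign_saav("AAATAAK", float("nan"), 3)

    def test_matches_brute_force_oracle_on_random_triples(self, rng):
        """Exhaustive scoring over all ordered residue pairs agrees with the
        implementation on randomized (peptide, shift, site) triples."""
        residues = np.array(list(STANDARD_AA))
        shifts = [e.shift for e in theoretical_saav_entries()]
        n_accept = n_origin = n_nopair = 0
        for i in range(1500):
            pep = "".join(rng.choice(residues, size=rng.integers(7, 20)))
            site = int(rng.integers(1, len(pep) + 1))
            mode = i % 3
            if mode == 0:  # exact theoretical shift
                dm = float(rng.choice(shifts))
            elif mode == 1:  # near-theoretical
                dm = float(rng.choice(shifts) + rng.normal(0, 0.05))
            else:  # anywhere
                dm = float(rng.uniform(-120, 120))
            got = assign_saav(pep, dm, site)
            want = brute_force_assign(pep, dm, site)
            if want[0] == "accept":
                assert got.accepted and (got.from_aa, got.to_aa) == want[1:]
                n_accept += 1
            else:
                assert not got.accepted and got.reject_reason == want[1]
                if want[1] == REJECT_ORIGIN:
                    n_origin += 1
                else:
                    n_nopair += 1
        # the sample exercised every outcome
        assert min(n_accept, n_origin, n_nopair) > 20

    def test_round_trip_over_catalog(self, small_sim):
        """Every catalog SAAV at its exact theoretical shift is re-called,
        with I/L destinations collapsed to X."""
        for p in small_sim.pairs[:500]:
            res = assign_saav(p.human_peptide, p.saav.delta_mass, p.site)
            assert res.accepted
            assert res.from_aa == p.saav.from_aa
            expected_to = "X" if p.saav.to_aa in "IL" else p.saav.to_aa
            assert res.to_aa == expected_to

    def test_tolerance_monotonicity(self, rng):
        """Accepted set at a tighter tolerance is a subset of the accepted
        set at a looser one."""
        residues = np.array(list(STANDARD_AA))
        for _ in range(200):
            pep = "".join(rng.choice(residues, size=10))
            dm = float(rng.normal(0, 30))
            site = int(rng.integers(1, 11))
            tight = assign_saav(pep, dm, site, tolerance=0.02)
            loose = assign_saav(pep, dm, site, tolerance=0.5)
            if tight.accepted:
                assert loose.accepted
                assert (tight.from_aa, tight.to_aa) == (loose.from_aa, loose.to_aa)


class TestAssignSaavTable:
    def test_agrees_with_scalar_assignment(self, rng):
        residues = np.array(list(STANDARD_AA))
        rows = []
        for _ in range(300):
            pep = "".join(rng.choice(residues, size=12))
            rows.append(
                {
                    "sample_id": "s1",
                    "spectrum_id": f"sp{len(rows)}",
                    "tool": "t",
                    "peptide": pep,
                    "delta_mass": float(rng.normal(0, 30)),
                    "site": int(rng.integers(1, 13)),
                }
            )
        df = normalize_psm_table(pd.DataFrame(rows))
        out = assign_saav_table(df)
        for row in out.itertuples(index=False):
            want = assign_saav(row.peptide, row.delta_mass, int(row.site))
            if want.accepted:
                assert row.reject_reason == ""
                assert (row.from_aa, row.to_aa) == (want.from_aa, want.to_aa)
            else:
                assert row.reject_reason == want.reject_reason

    def test_accepted_rows_satisfy_criteria_post_hoc(self, small_sim):
        df = normalize_psm_table(small_sim.open_psms["open_a"])
        df = filter_localized_psms(df, "generic")
        out = accepted_candidates(assign_saav_table(df))
        assert len(out) > 0
        assert (out["delta_delta_mass"] < 0.1).all()
        origins = [p[int(s) - 1] for p, s in zip(out["peptide"], out["site"])]
        assert (out["from_aa"] == origins).all()

    def test_preassigned_saavs_bypass_search_but_check_origin(self):
        df = pd.DataFrame(
            {
                "sample_id": ["s1", "s1"],
                "spectrum_id": ["sp1", "sp2"],
                "tool": ["pfind", "pfind"],
                "peptide": ["VLDELTK", "VLDELTK"],
                "delta_mass": [14.01565, 14.01565],
                "site": [1, 2],
                "preassigned": [True, True],
                "preassigned_from": ["V", "V"],
                "preassigned_to": ["I", "I"],
            }
        )
        out = assign_saav_table(normalize_psm_table(df))
        ok, bad = out.iloc[0], out.iloc[1]
        assert ok.reject_reason == "" and (ok.from_aa, ok.to_aa) == ("V", "X")
        assert bad.reject_reason == REJECT_ORIGIN  # site 2 is L, not V


class TestNormalizeAndFilter:
    def test_generic_tsv_round_trip(self, tmp_path):
        f = tmp_path / "psms.tsv"
        f.write_text(
            "sample_id\tspectrum_id\tpeptide\tdelta_mass\tsite\tretention_time\n"
            "s1\tsp1\tVLDELTK\t14.0157\t1\t30.5\n"
        )
        df = normalize_psm_table(f, tool="t")
        assert list(df["peptide"]) == ["VLDELTK"]
        assert df["retention_time"].iloc[0] == 30.5

    def test_unknown_dialect_lists_available(self):
        with pytest.raises(ValueError, match="generic"):
            normalize_psm_table(pd.DataFrame(), dialect="foo")

    def test_missing_mandatory_column_named(self):
        df = pd.DataFrame({"sample_id": ["s1"], "spectrum_id": ["sp1"]})
        with pytest.raises(ValueError, match="peptide"):
            normalize_psm_table(df)

    def test_rows_missing_mandatory_fields_dropped(self):
        df = pd.DataFrame(
            {
                "sample_id": ["s1", "s1"],
                "spectrum_id": ["sp1", None],
                "peptide": ["AAAK", "CCCK"],
            }
        )
        assert len(normalize_psm_table(df)) == 1

    def test_msfragger_lowercase_localization(self):
        df = pd.DataFrame(
            {
                "sample_id": ["s1", "s1"],
                "Spectrum": ["sp1", "sp2"],
                "Peptide": ["VLDELTK", "VLDELTK"],
                "Delta Mass": [14.0157, 14.0157],
                "MSFragger Localization": ["vLDELTK", "vlDELTK"],
            }
        )
        out = normalize_psm_table(df, dialect="msfragger_open")
        assert out["site"].iloc[0] == 1
        assert pd.isna(out["site"].iloc[1])  # two lowercase letters: ambiguous
        kept = filter_localized_psms(out, "msfragger")
        assert list(kept["spectrum_id"]) == ["sp1"]

    def test_maxquant_policy_strict_probability(self):
        df = pd.DataFrame(
            {
                "sample_id": ["s1"] * 3,
                "spectrum_id": ["sp1", "sp2", "sp3"],
                "peptide": ["VLDELTK"] * 3,
                "delta_mass": [14.0157] * 3,
                "site": [1, 1, None],
                "site_probability": [0.51, 0.50, 0.9],
            }
        )
        out = filter_localized_psms(normalize_psm_table(df), "maxquant_dp")
        # 0.50 fails the strict > 0.5 rule; missing site always fails
        assert list(out["spectrum_id"]) == ["sp1"]

    def test_generic_policy_requires_site(self):
        df = pd.DataFrame(
            {
                "sample_id": ["s1", "s1"],
                "spectrum_id": ["sp1", "sp2"],
                "peptide": ["VLDELTK"] * 2,
                "delta_mass": [14.0157] * 2,
                "site": [3, None],
            }
        )
        out = filter_localized_psms(normalize_psm_table(df), "generic")
        assert list(out["spectrum_id"]) == ["sp1"]
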