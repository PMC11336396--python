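import numpy as np
import pytest

from taxodiag.alignment import RegionMap
from taxodiag.diagnosis import (
    DiagnosisConfig,
    DistanceProfile,
    WindowSpec,
    audit_printed_diagnoses,
    enumerate_windows,
    estimate_species_count,
    find_diagnoses,
    format_diagnosis,
    format_fragment,
    hamming_window,
    load_printed_diagnoses,
    mismatch_allowance,
    parse_fragment,
    printed_fragment,
    validate_diagnosis,
    window_profile,
    within_group_variability,
)

from conftest import make_alignment, random_alignment
from oracles import best_window, single_linkage_clusters, window_hamming


class TestHammingWindow:
    @pytest.mark.parametrize("other,expected", [
        ("ACGTACGTAC", 0),       # identity
        ("AGGAACGTAC", 2),       # two substitutions in window
        ("AC-TACGTAC", 1),       # gap against base counts once
        ("RCGTACGTAC", 0),       # R covers A: lenient match
    ])
    def test_examples(self, other, expected):
        aln = make_alignment({"ref": "ACGTACGTAC", "oth": other})
        assert hamming_window(aln, WindowSpec(1, 4), "ref", "oth") == expected

    def test_matches_column_loop_oracle(self):
        rng = np.random.default_rng(3)
        aln = random_alignment(rng, 6, 80, 2, gap_frac=0.05, ambig_frac=0.02)
        a, b = aln.members[0], aln.members[1]
        for start, length in [(1, 20), (30, 25), (51, 30)]:
            assert hamming_window(aln, WindowSpec(start, length),
                                  a.accession, b.accession) == \
                window_hamming(a.residues, b.residues, start, length)


class TestEnumerateWindows:
    def test_window_counts(self):
        aln = make_alignment({"a": "A" * 120, "b": "C" * 120})
        rm = RegionMap({"R": (11, 110)}, 120)
        # 100-column region, lengths 20..30: sum_{L}(101-L) = 836
        assert sum(1 for _ in enumerate_windows(aln, rm, "R")) == 836
        rm30 = RegionMap({"R": (1, 30)}, 120)
        assert sum(1 for _ in enumerate_windows(aln, rm30, "R", 30, 30)) == 1
        rm19 = RegionMap({"R": (1, 19)}, 120)
        assert sum(1 for _ in enumerate_windows(aln, rm19, "R")) == 0

    def test_ordering_start_then_length(self):
        aln = make_alignment({"a": "A" * 50, "b": "C" * 50})
        rm = RegionMap({"R": (1, 44)}, 50)
        windows = list(enumerate_windows(aln, rm, "R", 20, 22))
        assert windows[0] == WindowSpec(1, 20)
        assert windows[1] == WindowSpec(1, 21)
        assert windows[3] == WindowSpec(2, 20)


class TestWindowProfile:
    def test_constructed_separation(self):
        base = "ACGT" * 10
        aln = make_alignment(
            {"t1": base, "t2": base, "n1": base[:2] + "TA" + base[4:]},
            species={"t1": "sp", "t2": "sp", "n1": "x"})
        prof = window_profile(aln, WindowSpec(1, 20), "sp")
        assert (prof.d_in, prof.d_out) == (0, 2)
        assert prof.nearest_out == "n1"

    def test_ambiguity_counted_and_rejected_by_search(self):
        base = "ACGT" * 10
        noisy = base[:5] + "N" + base[6:]
        aln = make_alignment(
            {"t1": noisy, "t2": base, "n1": "TGCA" * 10},
            species={"t1": "sp", "t2": "sp", "n1": "x"})
        prof = window_profile(aln, WindowSpec(1, 20), "sp", canonical="t1")
        assert prof.ambiguous_in_target >= 1
        rm = RegionMap({"R": (1, 40)}, 40)
        diags, _ = find_diagnoses(aln, "sp", rm, ["R"],
                                  DiagnosisConfig(l_min=20, l_max=20))
        for d in diags:
            assert not (d.window.start_column <= 6 <= d.window.end_column)

    def test_brute_force_equivalence(self):
        rng = np.random.default_rng(17)
        aln = random_alignment(rng, 12, 200, 4, gap_frac=0.02)
        for window in [WindowSpec(1, 25), WindowSpec(100, 30), WindowSpec(171, 30)]:
            prof = window_profile(aln, window, "sp01")
            seqs = {m.accession: m.residues for m in aln.members}
            targets = aln.members_of("sp01")
            canon = seqs[targets[0]]
            d_in = max(window_hamming(canon, seqs[t], window.start_column,
                                      window.length) for t in targets)
            d_out = min(window_hamming(canon, seqs[a], window.start_column,
                                       window.length)
                        for a in seqs if a not in set(targets))
            assert (prof.d_in, prof.d_out) == (d_in, d_out)


class TestMismatchAllowance:
    @pytest.mark.parametrize("d_in,d_out,interval,reported", [
        (0, 2, (0, 1), 1),   # "one mismatch allowed"
        (0, 1, (0, 0), 0),   # "no mismatch allowed"
        (1, 3, (1, 2), 1),
        (2, 5, (2, 4), 2),   # cap below d_in floors at d_in
        (2, 2, None, None),  # not diagnostic
    ])
    def test_interval_and_reported(self, d_in, d_out, interval, reported):
        prof = DistanceProfile(d_in, d_out, "x", 0)
        assert mismatch_allowance(prof, cap=1) == (interval, reported)


class TestFindDiagnoses:
    def test_inseparable_reports_no_separation(self):
        base = "ACGT" * 15
        aln = make_alignment({"t1": base, "n1": base, "n2": "TTTT" + base[4:]},
                             species={"t1": "sp", "n1": "x", "n2": "y"})
        rm = RegionMap({"R": (1, 60)}, 60)
        diags, failures = find_diagnoses(aln, "sp", rm, ["R"])
        assert diags == []
        assert failures[0].reason == "no separation"
        assert failures[0].best_margin is not None

    def test_planted_window_recovered(self, planted_dataset):
        ds = planted_dataset
        diags, _ = find_diagnoses(ds.alignment, "sp01", ds.region_map,
                                  [ds.truth.planted.region])
        assert diags, "planted diagnosis must be found"
        w = diags[0].window
        c0, c1 = ds.truth.planted.window_columns
        assert w.start_column <= c1 and c0 <= w.end_column, \
            "top window must overlap the planted window"

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(23)
        for rep in range(10):
            n_seqs = int(rng.integers(5, 12))
            n_cols = int(rng.integers(90, 200))
            aln = random_alignment(rng, n_seqs, n_cols, max(2, n_seqs // 3),
                                   gap_frac=0.02, ambig_frac=0.01)
            rm = RegionMap({"R": (1, n_cols)}, n_cols)
            diags, _ = find_diagnoses(aln, "sp01", rm, ["R"])
            seqs = {m.accession: m.residues for m in aln.members}
            expected = best_window(seqs, aln.members_of("sp01"),
                                   aln.members_of("sp01")[0], (1, n_cols))
            if expected is None:
                assert diags == []
            else:
                s, length, d_in, d_out = expected
                d = diags[0]
                assert (d.window.start_column, d.window.length) == (s, length)
                assert d.margin == d_out - d_in

    def test_monotonicity_of_separation(self):
        """Adding non-targets can only shrink d_out; adding targets can
        only grow d_in."""
        rng = np.random.default_rng(29)
        aln_small = random_alignment(rng, 8, 120, 4)
        window = WindowSpec(11, 25)
        prof_small = window_profile(aln_small, window, "sp01")
        extra = make_alignment(
            {m.accession: m.residues for m in aln_small.members} |
            {"extra": aln_small.members[1].residues},
            species={m.accession: m.label("species")
                     for m in aln_small.members} | {"extra": "spX"})
        prof_more_out = window_profile(extra, window, "sp01")
        assert prof_more_out.d_out <= prof_small.d_out
        extra_t = make_alignment(
            {m.accession: m.residues for m in aln_small.members} |
            {"extra": aln_small.members[-1].residues},
            species={m.accession: m.label("species")
                     for m in aln_small.members} | {"extra": "sp01"})
        prof_more_in = window_profile(extra_t, window, "sp01")
        assert prof_more_in.d_in >= prof_small.d_in

    def test_emitted_diagnosis_validates(self, planted_dataset):
        ds = planted_dataset
        diags, _ = find_diagnoses(ds.alignment, "sp02", ds.region_map)
        for d in diags:
            report = validate_diagnosis(ds.alignment, d, ds.region_map)
            assert report.ok, (d.region, report)

    def test_lowered_allowance_breaks_target_check(self):
        base = "ACGT" * 15
        variant = base[:3] + "A" + base[4:]
        aln = make_alignment({"t1": base, "t2": variant,
                              "n1": "TGCATGCA" + base[8:]},
                             species={"t1": "sp", "t2": "sp", "n1": "x"})
        rm = RegionMap({"R": (1, 60)}, 60)
        diags, _ = find_diagnoses(aln, "sp", rm, ["R"],
                                  DiagnosisConfig(allowance_cap=1))
        d = next(d for d in diags if d.allowance_interval[0] >= 1)
        d.reported_allowance = d.allowance_interval[0] - 1
        report = validate_diagnosis(aln, d, rm)
        assert not report.target_within_allowance


class TestVariability:
    def test_identical_sequences(self):
        aln = make_alignment({f"s{i}": "ACGT" * 10 for i in range(3)},
                             species={f"s{i}": "sp" for i in range(3)})
        rm = RegionMap({"full": (1, 40)}, 40)
        rep = within_group_variability(aln, "sp", "full", rm)
        assert rep.max_pairwise == 0.0
        assert rep.n_sequences == 3

    def test_direct_count(self):
        a = "A" * 200
        b = "C" * 7 + "A" * 193
        aln = make_alignment({"s1": a, "s2": b, "o": "G" * 200},
                             species={"s1": "sp", "s2": "sp", "o": "x"})
        rm = RegionMap({"full": (1, 200)}, 200)
        rep = within_group_variability(aln, "sp", "full", rm)
        assert rep.max_pairwise == pytest.approx(0.035)

    def test_single_member_flagged(self):
        aln = make_alignment({"s1": "ACGT", "o": "TTTT"},
                             species={"s1": "sp", "o": "x"})
        rm = RegionMap({"full": (1, 4)}, 4)
        rep = within_group_variability(aln, "sp", "full", rm)
        assert rep.single_sequence and rep.max_pairwise == 0.0

    def test_matches_truth_record(self, planted_dataset):
        ds = planted_dataset
        for sp, expected in ds.truth.max_within_divergence.items():
            rep = within_group_variability(ds.alignment, sp, "full",
                                           ds.region_map)
            assert rep.max_pairwise == pytest.approx(expected, abs=1e-12)


class TestSpeciesCount:
    def test_three_clusters(self):
        rng = np.random.default_rng(31)
        base = "".join(np.array(list("ACGT"), dtype="U1")[
            rng.integers(0, 4, 300)])

        def mutate(s, k, seed):
            r = np.random.default_rng(seed)
            chars = np.array(list(s), dtype="U1")
            for pos in r.choice(300, size=k, replace=False):
                chars[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[chars[pos]]
            return "".join(chars)

        groups = [base, mutate(base, 30, 1), mutate(base, 60, 2)]
        rows, genus = {}, {}
        for g, centre in enumerate(groups):
            for j in range(2):
                acc = f"g{g}s{j}"
                rows[acc] = mutate(centre, 2, 10 * g + j)  # intra <= ~1.3%
                genus[acc] = "Genus"
        rows["out"] = mutate(base, 150, 99)
        aln = make_alignment(rows, genus={k: v for k, v in genus.items()})
        rm = RegionMap({"full": (1, 300)}, 300)
        count, clusters = estimate_species_count(aln, "Genus", "full", rm,
                                                 threshold=0.03)
        assert count == 3
        members = aln.members_of("Genus", "genus")
        oracle = single_linkage_clusters(
            members,
            lambda a, b: sum(x != y for x, y in zip(rows[a], rows[b])) / 300,
            0.03)
        assert count == oracle

    def test_monotone_in_threshold(self, planted_dataset):
        ds = planted_dataset
        counts = [estimate_species_count(ds.alignment, "gen01", "full",
                                         ds.region_map, threshold=t)[0]
                  for t in (0.001, 0.01, 0.05, 0.2)]
        assert counts == sorted(counts, reverse=True)


class TestDiagnosisFormat:
    def test_printed_fragment_styles(self):
        assert format_fragment("ITS2", 127, 146, "gaaccgcaaattacgcatta", 1, ",") \
            == "ITS2 positions 127–146 gaaccgcaaattacgcatta, one mismatch allowed"
        assert format_fragment("", 87, 106,
                               "actgagccttgcagcaacaatctccccttt", 0) \
            == ("positions 87–106 actgagccttgcagcaacaatctccccttt; "
                "no mismatch allowed")

    def test_formatter_parser_round_trip_on_all_printed(self):
        df = load_printed_diagnoses()
        assert df["species"].nunique() == 15
        for _, row in df.iterrows():
            frag = printed_fragment(row)
            parsed = parse_fragment(frag)
            rebuilt = format_fragment(parsed["region_prefix"], parsed["start"],
                                      parsed["end"], parsed["barcode"],
                                      parsed["allowance"], parsed["separator"])
            assert rebuilt == frag

    def test_full_sentence_template(self, planted_dataset):
        ds = planted_dataset
        diags, _ = find_diagnoses(ds.alignment, "sp01", ds.region_map,
                                  ["ITS2", "LSU"])
        its = next((d for d in diags if d.region == "ITS2"), None)
        lsu = next((d for d in diags if d.region == "LSU"), None)
        text = format_diagnosis("Genusa", its, lsu)
        assert text.startswith("Separation from other species of *Genusa* "
                               "based on the ITS region (ITS2 positions ")
        if lsu is not None:
            assert " and LSU (positions " in text

    def test_audit_flags_known_inconsistencies(self):
        audit = audit_printed_diagnoses()
        bad = audit.loc[~audit["length_consistent"]]
        assert set(bad["species"]) == {"Hoforsa rebekkae", "Langduoa dianae"}
        dup = audit.loc[audit["duplicate_barcode"] & (audit["marker"] == "ITS")]
        assert set(dup["species"]) == {"Langduoa dianae", "Parnigua craigii"}
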