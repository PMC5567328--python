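import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from occbias import grid, snapshot, stats
from occbias.ingest import BackboneEntry, iter_records
from occbias.stats import (
    BiasDeviation,
    ClassSummary,
    deviation,
    ideal_sampling,
    mad,
    median,
    occurrence_class_histogram,
    share_of_total,
    summarize,
    temporal_deviations,
    weighted_precision,
)


def brute_force_summary(records_df, backbone, taxon, level="class"):
    """Exhaustive per-record recomputation of every summary statistic."""
    key = "class_name" if level == "class" else "order_name"
    recs = [r for r in iter_records(records_df) if getattr(r, key) == taxon and taxon]
    nb_occ = len(recs)
    sp_counts = {}
    for r in recs:
        if r.species_precise and r.species:
            sp_counts[r.species] = sp_counts.get(r.species, 0) + 1
    counts = sorted(sp_counts.values())
    known = set()
    for e in backbone:
        if e.status != "synonym" and getattr(e, key) == taxon:
            known.add(e.species)
    n_gt20d = 0
    for sp, c in sp_counts.items():
        if c < 20:
            continue
        cells = set()
        for r in recs:
            if r.species == sp and r.lat is not None and r.lon is not None:
                p = grid.project_point(r.lat, r.lon)
                cell = grid.assign_cell_point(p)
                cells.add((cell.i, cell.j))
        if len(cells) >= 20:
            n_gt20d += 1

    def frac(pred):
        return sum(1 for r in recs if pred(r)) / nb_occ

    N = len(known)
    return {
        "nb_occ": nb_occ,
        "n_gt1": len(counts),
        "N": N,
        "med_sp": float(np.median(counts)) if counts else float("nan"),
        "mad": float(np.median(np.abs(np.array(counts) - np.median(counts))))
        if counts
        else float("nan"),
        "precision": frac(lambda r: r.species_precise),
        "p_gt1": len(counts) / N if N else float("nan"),
        "p_gt20": sum(1 for c in counts if c >= 20) / N if N else float("nan"),
        "p_gt20d": n_gt20d / N if N else float("nan"),
        "o_spec": frac(lambda r: r.origin == "Specimen"),
        "o_obs": frac(lambda r: r.origin == "Observation"),
        "o_unk": frac(lambda r: r.origin == "Unknown"),
        "p_time": frac(lambda r: r.time_issue),
        "p_space": frac(lambda r: r.space_issue),
    }


class TestMedianMad:
    def test_single_species_single_record(self):
        assert median([1]) == 1
        assert mad([1]) == 0

    def test_hand_computed(self):
        # three species at 1, 3, 100: median 3; |dev| = {2, 0, 97} -> mad 2
        assert median([1, 3, 100]) == 3
        assert mad([1, 3, 100]) == 2

    def test_even_length_half_integer(self):
        assert median([1, 2]) == 1.5

    @given(st.lists(st.integers(1, 10_000), min_size=1, max_size=50))
    @settings(max_examples=100, deadline=None)
    def test_permutation_invariance(self, values):
        rng = np.random.default_rng(0)
        perm = rng.permutation(values).tolist()
        assert median(perm) == median(values)
        assert mad(perm) == mad(values)


class TestIdealSampling:
    def test_single_class_identity(self):
        assert ideal_sampling(1000, 50, 50) == 1000

    def test_proportionality(self):
        assert ideal_sampling(1000, 250, 1000) == 250

    def test_zero_sum_symmetry(self):
        # two classes with equal N, occurrences 900 / 100 of 1000
        i = ideal_sampling(1000, 500, 1000)
        assert deviation(900, i) == 400
        assert deviation(100, i) == -400

    def test_domain(self):
        with pytest.raises(ValueError):
            ideal_sampling(10, 1, 0)
        with pytest.raises(ValueError):
            ideal_sampling(10, 5, 4)


class TestSummarize:
    def test_brute_force_agreement(self, dataset):
        records, backbone = dataset["records"], dataset["backbone"]
        assert len(records) <= 10_000
        summaries = summarize(records, backbone, level="class")
        assert len(summaries) == 3
        for s in summaries:
            expected = brute_force_summary(records, backbone, s.taxon)
            for field_name, want in expected.items():
                got = getattr(s, field_name)
                if isinstance(want, float) and np.isnan(want):
                    assert np.isnan(got)
                else:
                    assert got == pytest.approx(want), (s.taxon, field_name)

    def test_order_level_brute_force(self, dataset):
        records, backbone = dataset["records"], dataset["backbone"]
        summaries = summarize(records, backbone, level="order")
        assert summaries
        for s in summaries[:4]:
            expected = brute_force_summary(records, backbone, s.taxon, level="order")
            assert s.nb_occ == expected["nb_occ"]
            assert s.med_sp == pytest.approx(expected["med_sp"])
            assert s.p_gt20d == pytest.approx(expected["p_gt20d"])

    def test_precision_within_3se(self, dataset, small_config):
        records, backbone = dataset["records"], dataset["backbone"]
        summaries = {s.taxon: s for s in summarize(records, backbone)}
        for spec in small_config.classes:
            s = summaries[spec.name]
            se = np.sqrt(spec.precision_rate * (1 - spec.precision_rate) / s.nb_occ)
            assert abs(s.precision - spec.precision_rate) <= max(3 * se, 1e-12)

    def test_p20d_never_exceeds_p20(self, dataset):
        for s in summarize(dataset["records"], dataset["backbone"]):
            assert s.p_gt20d <= s.p_gt20 + 1e-12
            assert s.p_gt20 <= s.p_gt1 + 1e-12

    def test_record_order_invariance(self, dataset):
        records = dataset["records"]
        shuffled = records.sample(frac=1.0, random_state=5).reset_index(drop=True)
        a = summarize(records, dataset["backbone"])
        b = summarize(shuffled, dataset["backbone"])
        assert {s.taxon: s.med_sp for s in a} == {s.taxon: s.med_sp for s in b}
        assert {s.taxon: s.mad for s in a} == {s.taxon: s.mad for s in b}

    def test_bad_level(self, dataset):
        with pytest.raises(ValueError):
            summarize(dataset["records"], dataset["backbone"], level="family")


class TestTemporalDeviations:
    def _df(self, rows):
        df = pd.DataFrame(rows, columns=["class_name", "year"])
        df["year"] = df["year"].astype("Int64")
        return df

    def _bb(self, counts):
        out = []
        for cls, n in counts.items():
            out += [BackboneEntry(f"{cls} sp{i}", cls, "", "accepted") for i in range(n)]
        return out

    def test_all_undated(self):
        df = self._df([("A", None)] * 5 + [("B", None)] * 5)
        devs = temporal_deviations(df, self._bb({"A": 10, "B": 10}))
        assert all(d.D == 0 for d in devs)
        assert all(d.nb_occ == 0 for d in devs)

    def test_constant_before_first_checkpoint(self):
        df = self._df([("A", 1940)] * 30 + [("B", 1950)] * 10)
        devs = temporal_deviations(df, self._bb({"A": 10, "B": 10}))
        by_cp = {}
        for d in devs:
            by_cp.setdefault(d.taxon, []).append(d.D)
        for taxon, ds in by_cp.items():
            assert len(set(ds)) == 1

    def test_last_decade_excluded(self):
        df = self._df([("A", 2010)] * 50 + [("A", 1950)] * 2 + [("B", 1950)] * 2)
        devs = temporal_deviations(df, self._bb({"A": 10, "B": 10}), export_year=2016)
        at_2006 = [d for d in devs if d.checkpoint == 2006]
        assert sum(d.nb_occ for d in at_2006) == 4

    def test_zero_sum_at_every_checkpoint(self, dataset):
        devs = temporal_deviations(dataset["records"], dataset["backbone"])
        by_cp = {}
        for d in devs:
            by_cp.setdefault(d.checkpoint, []).append(d)
        for cp, ds in by_cp.items():
            nb = sum(d.nb_occ for d in ds)
            assert abs(sum(d.D for d in ds)) <= 1e-6 * max(nb, 1)

    def test_faster_accumulation_grows_deviation(self):
        # class A accumulates faster after 1975: |D_A| non-decreasing after
        rows = []
        for year in range(1900, 2007):
            rows += [("A", year)] * (1 if year < 1975 else 8)
            rows += [("B", year)] * 1
        df = self._df(rows)
        devs = temporal_deviations(df, self._bb({"A": 10, "B": 10}))
        d_a = [d.D for d in devs if d.taxon == "A" and d.checkpoint >= 1976]
        assert all(b >= a - 1e-9 for a, b in zip(d_a, d_a[1:]))
        # brute-force recount at one checkpoint
        at_1996 = next(d for d in devs if d.taxon == "A" and d.checkpoint == 1996)
        manual = sum(1 for cls, y in rows if cls == "A" and y <= 1996)
        assert at_1996.nb_occ == manual

    def test_sign_consistency(self, dataset):
        devs = temporal_deviations(dataset["records"], dataset["backbone"])
        for d in devs:
            if d.D > 0:
                assert d.sign == "over"
            elif d.D < 0:
                assert d.sign == "under"
            else:
                assert d.sign == "balanced"


class TestHistogram:
    def test_published_counts(self):
        counts = []
        for value, n in zip((1, 2, 20), snapshot.SPECIES_HISTOGRAM_COUNTS):
            counts += [value] * n
        p1, pmid, p20 = occurrence_class_histogram(np.array(counts))
        assert round(p1, 2) == 0.21
        assert round(pmid, 2) == 0.44
        assert round(p20, 2) == 0.35
        assert p1 + pmid + p20 == pytest.approx(1.0)

    def test_single_species(self):
        assert occurrence_class_histogram([1]) == (1.0, 0.0, 0.0)

    def test_boundary_20_inclusive(self):
        assert occurrence_class_histogram([20]) == (0.0, 0.0, 1.0)

    def test_19_is_mid(self):
        assert occurrence_class_histogram([19]) == (0.0, 1.0, 0.0)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            occurrence_class_histogram([])


class TestWeightedPrecision:
    def test_published_rows_all(self):
        rows = snapshot.class_summaries()
        assert round(weighted_precision(rows), 2) == 0.94

    def test_published_rows_excluding_aves(self):
        rows = snapshot.class_summaries()
        assert round(weighted_precision(rows, exclude={"Aves"}), 2) == 0.88

    def test_single_taxon(self):
        s = ClassSummary(taxon="X", nb_occ=10, precision=0.73)
        assert weighted_precision([s]) == pytest.approx(0.73)

    def test_no_rows(self):
        with pytest.raises(ValueError):
            weighted_precision([], exclude=set())


class TestShareOfTotal:
    def test_published_aves_occurrence_share(self):
        rows = snapshot.class_summaries()
        share = share_of_total(rows, "Aves", snapshot.totals()["gbif"]["nb_occ_millions"])
        assert round(100 * share) == 53

    def test_whole_set_is_one(self):
        rows = [ClassSummary("A", nb_occ=3), ClassSummary("B", nb_occ=7)]
        assert share_of_total(rows, "A", 10) + share_of_total(rows, "B", 10) == 1.0

    def test_unknown_taxon(self):
        with pytest.raises(KeyError):
            share_of_total([ClassSummary("A", nb_occ=1)], "B", 1)
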