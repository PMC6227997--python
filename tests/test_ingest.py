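"""Reading, validating and summarising the three input streams."""

import collections
import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import baybudgets as bb
from baybudgets.core import DEFAULT_BAYS
from baybudgets.ingest import write_table

BAYS = list(DEFAULT_BAYS)


def _write(tmp_path, name, text):
    path = tmp_path / name
    path.write_text(text)
    return path


class TestReadSightings:
    def test_toy_csv_row_and_individual_counts(self, tmp_path):
        path = _write(
            tmp_path,
            "s.csv",
            "individual_id,date,bay\n"
            "A,2011-01-01,Makako\n"
            "A,2011-01-02,Kealakekua\n"
            "B,2011-01-01,Makako\n",
        )
        table = bb.read_sightings(path, BAYS)
        assert len(table) == 3
        assert table["individual_id"].nunique() == 2

    def test_unknown_bay_is_hard_error(self, tmp_path):
        path = _write(
            tmp_path, "s.csv", "individual_id,date,bay\nA,2011-01-01,Oahu\n"
        )
        with pytest.raises(bb.ValidationError, match="Oahu"):
            bb.read_sightings(path, BAYS)

    def test_unparseable_date_is_hard_error(self, tmp_path):
        path = _write(
            tmp_path, "s.csv", "individual_id,date,bay\nA,Jan 1st,Makako\n"
        )
        with pytest.raises(bb.ValidationError, match="date"):
            bb.read_sightings(path, BAYS)

    def test_duplicate_rows_collapse_with_warning(self, tmp_path, caplog):
        path = _write(
            tmp_path,
            "s.csv",
            "individual_id,date,bay\n"
            "A,2011-01-01,Makako\n"
            "A,2011-01-01,Makako\n",
        )
        with caplog.at_level(logging.WARNING, logger="baybudgets"):
            table = bb.read_sightings(path, BAYS)
        assert len(table) == 1
        assert any("duplicate" in r.message for r in caplog.records)

    def test_round_trip_is_identity(self, fixture_tables, tmp_path):
        sightings, _, _ = fixture_tables
        path = tmp_path / "rt.csv"
        write_table(sightings, path)
        again = bb.read_sightings(path, BAYS)
        pd.testing.assert_frame_equal(sightings, again)


class TestOccurrenceMatrix:
    def test_normalization_of_counts(self):
        rows = [("A", f"2011-01-0{d}", b) for d, b in
                [(1, "Makako"), (2, "Makako"), (3, "Makako"), (4, "Kealakekua")]]
        df = pd.DataFrame(rows, columns=["individual_id", "date", "bay"])
        df["date"] = pd.to_datetime(df["date"]).dt.date
        m = bb.occurrence_matrix(df, BAYS)
        np.testing.assert_allclose(
            m.probs.loc["A"].to_numpy(), [0.75, 0.25, 0.0, 0.0]
        )

    def test_single_sighting_degenerate_probability(self):
        df = pd.DataFrame(
            [("A", pd.Timestamp("2011-01-01").date(), "Honaunau")],
            columns=["individual_id", "date", "bay"],
        )
        m = bb.occurrence_matrix(df, BAYS)
        assert m.probs.loc["A", "Honaunau"] == 1.0
        assert m.probs.loc["A"].drop("Honaunau").eq(0).all()

    def test_matches_brute_force_tally(self, rng):
        # random sighting records, tallied independently with a Counter
        records = []
        for i in range(5):
            for _ in range(int(rng.integers(1, 15))):
                records.append(
                    (
                        f"I{i}",
                        pd.Timestamp("2011-01-01").date()
                        + pd.Timedelta(days=int(rng.integers(0, 200))),
                        BAYS[rng.integers(0, 4)],
                    )
                )
        df = pd.DataFrame(
            records, columns=["individual_id", "date", "bay"]
        ).drop_duplicates()
        tally = collections.Counter(
            (r.individual_id, r.bay) for r in df.itertuples()
        )
        m = bb.occurrence_matrix(df, BAYS)
        for ind in m.individuals:
            total = sum(tally[(ind, b)] for b in BAYS)
            for b in BAYS:
                assert m.counts.loc[ind, b] == tally[(ind, b)]
                assert m.probs.loc[ind, b] == pytest.approx(
                    tally[(ind, b)] / total
                )

    @given(
        counts=st.lists(
            st.lists(st.integers(0, 20), min_size=4, max_size=4).filter(
                lambda row: sum(row) > 0
            ),
            min_size=1,
            max_size=8,
        )
    )
    @settings(deadline=None, max_examples=50)
    def test_probability_rows_sum_to_one(self, counts):
        rows = []
        for i, row in enumerate(counts):
            for b, c in zip(BAYS, row):
                for d in range(c):
                    rows.append((f"I{i}", pd.Timestamp("2011-01-01").date()
                                 + pd.Timedelta(days=d), b))
        df = pd.DataFrame(rows, columns=["individual_id", "date", "bay"])
        m = bb.occurrence_matrix(df, BAYS)
        np.testing.assert_allclose(m.probs.sum(axis=1), 1.0, atol=1e-12)
        assert ((m.probs.to_numpy() == 0) == (m.counts.to_numpy() == 0)).all()


class TestBayUse:
    def test_fixture_hand_tally(self, fixture_tables, hand_tally):
        sightings, _, _ = fixture_tables
        m = bb.occurrence_matrix(sightings, BAYS)
        summary = bb.bay_use_summary(m).set_index("bay")
        for bay, pct in hand_tally["bay_use_pct"].items():
            assert summary.loc[bay, "pct_rounded"] == pct

    def test_single_bay_population(self):
        df = pd.DataFrame(
            [(f"I{i}", pd.Timestamp("2011-01-01").date(), "Makako")
             for i in range(7)],
            columns=["individual_id", "date", "bay"],
        )
        summary = bb.bay_use_summary(bb.occurrence_matrix(df, BAYS))
        by_bay = summary.set_index("bay")["pct"]
        assert by_bay["Makako"] == 100.0
        assert (by_bay.drop("Makako") == 0.0).all()

    def test_percentages_bounded_but_not_normalised(self, fixture_tables):
        sightings, _, _ = fixture_tables
        summary = bb.bay_use_summary(bb.occurrence_matrix(sightings, BAYS))
        assert summary["pct"].between(0, 100).all()


class TestReadAcoustic:
    def test_gap_fill_to_missing(self, fixture_tables, hand_tally):
        _, acoustic, _ = fixture_tables
        missing = (
            acoustic[acoustic["status"] == "MISSING"].groupby("bay").size()
        )
        for bay, n in hand_tally["missing_days"].items():
            assert missing.get(bay, 0) == n
        # every (bay, study day) resolves
        assert len(acoustic) == 4 * 12

    def test_bad_status_token_errors(self, tmp_path):
        path = _write(
            tmp_path, "a.csv", "bay,date,status\nMakako,2011-01-01,MAYBE\n"
        )
        with pytest.raises(bb.ValidationError, match="MAYBE"):
            bb.read_acoustic(path, BAYS, [pd.Timestamp("2011-01-01").date()])

    def test_presence_probability_fixture(self, fixture_tables, hand_tally):
        _, acoustic, _ = fixture_tables
        for bay, p in hand_tally["presence_probability"].items():
            assert bb.presence_probability(acoustic, bay) == pytest.approx(p)

    def test_presence_probability_brute_force(self, rng):
        statuses = rng.choice(
            ["PRESENT", "ABSENT", "MISSING"], size=60, p=[0.5, 0.3, 0.2]
        )
        df = pd.DataFrame(
            {
                "bay": "Makako",
                "date": [
                    pd.Timestamp("2011-01-01").date() + pd.Timedelta(days=i)
                    for i in range(60)
                ],
                "status": statuses,
            }
        )
        n_present = sum(1 for s in statuses if s == "PRESENT")
        n_obs = sum(1 for s in statuses if s != "MISSING")
        assert bb.presence_probability(df, "Makako") == pytest.approx(
            n_present / n_obs
        )

    def test_all_missing_errors(self):
        df = pd.DataFrame(
            {
                "bay": ["Makako"],
                "date": [pd.Timestamp("2011-01-01").date()],
                "status": ["MISSING"],
            }
        )
        with pytest.raises(bb.ValidationError, match="prior"):
            bb.presence_probability(df, "Makako")


class TestReadScans:
    def test_fixture_parses_ordered(self, fixture_tables):
        _, _, scans = fixture_tables
        assert len(scans) == 21
        grouped = scans.groupby("follow_id")["timestamp"]
        assert (grouped.apply(lambda s: s.is_monotonic_increasing)).all()

    def test_unknown_activity_token_errors(self, tmp_path):
        path = _write(
            tmp_path,
            "sc.csv",
            "follow_id,timestamp,platform,location,activity,"
            "n_boats,n_kayaks,n_swimmers\n"
            "F1,2011-01-01T08:00,BOAT,Makako,MILL,0,0,0\n",
        )
        with pytest.raises(bb.ValidationError, match="MILL"):
            bb.read_scans(path, BAYS)

    def test_negative_count_errors(self, tmp_path):
        path = _write(
            tmp_path,
            "sc.csv",
            "follow_id,timestamp,platform,location,activity,"
            "n_boats,n_kayaks,n_swimmers\n"
            "F1,2011-01-01T08:00,BOAT,Makako,REST,-1,0,0\n",
        )
        with pytest.raises(bb.ValidationError, match="n_boats"):
            bb.read_scans(path, BAYS)

    def test_duplicate_timestamp_within_follow_errors(self, tmp_path):
        path = _write(
            tmp_path,
            "sc.csv",
            "follow_id,timestamp,platform,location,activity,"
            "n_boats,n_kayaks,n_swimmers\n"
            "F1,2011-01-01T08:00,BOAT,Makako,REST,0,0,0\n"
            "F1,2011-01-01T08:00,BOAT,Makako,REST,0,0,0\n",
        )
        with pytest.raises(bb.ValidationError, match="non-increasing"):
            bb.read_scans(path, BAYS)

    def test_shuffled_rows_sort_identically(self, fixture_tables, tmp_path, rng):
        _, _, scans = fixture_tables
        shuffled = scans.sample(frac=1.0, random_state=3)
        path = tmp_path / "shuf.csv"
        out = shuffled.copy()
        out["timestamp"] = out["timestamp"].map(lambda t: t.isoformat())
        out.to_csv(path, index=False)
        again = bb.read_scans(path, BAYS)
        pd.testing.assert_frame_equal(scans, again)
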