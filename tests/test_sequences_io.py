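"""Deployment loading, 60 s grouping, annotation and filtered copies."""

import shutil
from pathlib import Path

import numpy as np
import pytest
from PIL import Image

from trapscan import sequence_labeling as sl
from trapscan import sequences_io as sio


def frames_at(times):
    return [
        sio.Frame(image_path=Path(f"im{i}.jpg"), pixels=np.zeros((40, 40), np.uint8), timestamp=float(t))
        for i, t in enumerate(times)
    ]


def reference_grouping(times, max_gap=60.0):
    """Independent single-pass chain-rule partition of sorted timestamps."""
    groups, cur = [], [times[0]]
    for t in times[1:]:
        if t - cur[-1] <= max_gap:
            cur.append(t)
        else:
            groups.append(cur)
            cur = [t]
    groups.append(cur)
    return groups


class TestGrouping:
    def test_small_gaps_single_sequence(self):
        seqs = sio.group_into_sequences(frames_at([0, 10, 20, 30]))
        assert len(seqs) == 1 and seqs[0].n_frames == 4

    def test_chain_rule_split(self):
        seqs = sio.group_into_sequences(frames_at([0, 59, 130]))
        assert [s.n_frames for s in seqs] == [2, 1]

    def test_boundary_60_joined_61_split(self):
        assert len(sio.group_into_sequences(frames_at([0, 60]))) == 1
        assert len(sio.group_into_sequences(frames_at([0, 61]))) == 2

    def test_singleton(self):
        seqs = sio.group_into_sequences(frames_at([42]))
        assert len(seqs) == 1 and seqs[0].frames[0].frame_index == 0

    def test_partition_property(self, rng):
        times = np.sort(rng.uniform(0, 5000, 200))
        frames = frames_at(times)
        seqs = sio.group_into_sequences(frames)
        flat = [f for s in seqs for f in s.frames]
        assert len(flat) == len(frames)
        assert {id(f) for f in flat} == {id(f) for f in frames}

    def test_matches_reference_implementation(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 40))
            times = np.sort(rng.choice(np.arange(0, 3000), size=n, replace=False)).astype(float)
            seqs = sio.group_into_sequences(frames_at(times))
            ref = reference_grouping(list(times))
            assert [s.n_frames for s in seqs] == [len(g) for g in ref]

    def test_idempotent_given_sorted_input(self, rng):
        times = np.sort(rng.uniform(0, 2000, 50))
        a = sio.group_into_sequences(frames_at(times))
        b = sio.group_into_sequences(frames_at(times))
        assert [s.n_frames for s in a] == [s.n_frames for s in b]


class TestLoadDeployment:
    def test_loads_and_sorts_by_exif_time(self, deployment):
        folder, manifest = deployment
        frames = sio.load_deployment(folder, "exif")
        n_expected = sum(s["n_frames"] for s in manifest["sequences"])
        assert len(frames) == n_expected
        ts = [f.timestamp for f in frames]
        assert ts == sorted(ts)

    def test_filename_timestamps_agree_with_exif(self, deployment):
        folder, _ = deployment
        by_exif = sio.load_deployment(folder, "exif")
        by_name = sio.load_deployment(folder, "filename")
        assert [f.image_path.name for f in by_exif] == [f.image_path.name for f in by_name]

    def test_corrupt_file_skipped_with_warning(self, deployment, tmp_path, caplog):
        folder, _ = deployment
        dest = tmp_path / "dep"
        dest.mkdir()
        for p in sorted(folder.glob("seq00_*.jpg"))[:5]:
            shutil.copyfile(p, dest / p.name)
        (dest / "broken_20230601_120000.jpg").write_bytes(b"not a jpeg")
        with caplog.at_level("WARNING"):
            frames = sio.load_deployment(dest, "filename")
        assert len(frames) == 5
        assert any("unreadable" in r.message for r in caplog.records)

    def test_empty_folder(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="no images"):
            sio.load_deployment(tmp_path)

    def test_unknown_source(self, deployment):
        with pytest.raises(ValueError):
            sio.load_deployment(deployment[0], "gps")


def _sequence_from(folder, pattern):
    frames = [
        f for f in sio.load_deployment(folder, "filename") if f.image_path.name.startswith(pattern)
    ]
    for i, f in enumerate(frames):
        f.frame_index = i
    return sio.SequenceRecord(sequence_id=pattern, frames=frames)


class TestWriteAnnotated:
    def test_box_colors_blue_human_red_animal(self, deployment, tmp_path):
        folder, _ = deployment
        seq = _sequence_from(folder, "seq00")
        dets = [[] for _ in seq.frames]
        dets[0] = [
            sl.Detection(0, (50, 50, 150, 120), "animal", 0.9),
            sl.Detection(0, (300, 200, 380, 330), "human", 0.8),
        ]
        written = sio.write_annotated(seq, dets, tmp_path)
        assert len(written) == len(seq.frames)
        img = np.asarray(Image.open(written[0]).convert("RGB")).astype(int)
        # animal box edge pixels dominated by red, human by blue
        edge_a = img[50:53, 50:150]
        assert edge_a[..., 0].mean() > edge_a[..., 2].mean() + 100
        edge_h = img[200:203, 300:380]
        assert edge_h[..., 2].mean() > edge_h[..., 0].mean() + 100

    def test_background_frame_copied_byte_identical(self, deployment, tmp_path):
        folder, _ = deployment
        seq = _sequence_from(folder, "seq03")
        dets = [[] for _ in seq.frames]
        written = sio.write_annotated(seq, dets, tmp_path)
        assert written[0].read_bytes() == seq.frames[0].image_path.read_bytes()


def _report_from_labels(folder, labels):
    results = []
    for pattern, label in labels.items():
        seq = _sequence_from(folder, pattern)
        results.append(
            sio.SequenceResult(
                sequence_id=pattern, label=label, frames=seq.frames,
                detections_per_frame=[[] for _ in seq.frames],
            )
        )
    return sio.DeploymentReport(deployment_id="dep", results=results)


class TestReportAndFilter:
    LABELS = {
        "seq00": "animal", "seq01": "animal", "seq02": "human",
        "seq03": "background", "seq04": "background", "seq05": "background",
    }

    def test_report_row_per_sequence_and_totals(self, deployment, tmp_path):
        report = _report_from_labels(deployment[0], self.LABELS)
        csv_path, txt_path = sio.write_report(report, tmp_path)
        import pandas as pd

        df = pd.read_csv(csv_path)
        assert len(df) == 6
        assert report.totals() == {"animal": 2, "human": 1, "background": 3}
        assert "background: 3" in txt_path.read_text()

    def test_filter_drops_human_and_background(self, deployment, tmp_path):
        report = _report_from_labels(deployment[0], self.LABELS)
        kept = sio.filter_deployment(report, {"background", "human"}, tmp_path / "filtered")
        assert kept == ["seq00", "seq01"]
        copied = sorted((tmp_path / "filtered").rglob("*.jpg"))
        assert len(copied) == 20

    def test_filter_copies_are_byte_identical(self, deployment, tmp_path):
        report = _report_from_labels(deployment[0], self.LABELS)
        sio.filter_deployment(report, {"background", "human"}, tmp_path / "f")
        src = report.results[0].frames[0].image_path
        dst = tmp_path / "f" / "seq00" / src.name
        assert dst.read_bytes() == src.read_bytes()

    def test_empty_drop_copies_all(self, deployment, tmp_path):
        report = _report_from_labels(deployment[0], self.LABELS)
        kept = sio.filter_deployment(report, set(), tmp_path / "all")
        assert len(kept) == 6

    def test_background_drop_on_six_sequence_fixture(self, deployment, tmp_path):
        report = _report_from_labels(deployment[0], self.LABELS)
        kept = sio.filter_deployment(report, {"background"}, tmp_path / "nb")
        assert len(kept) == 3

    def test_dest_inside_source_refused(self, deployment):
        report = _report_from_labels(deployment[0], self.LABELS)
        with pytest.raises(ValueError, match="inside"):
            sio.filter_deployment(report, set(), deployment[0] / "sub")
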