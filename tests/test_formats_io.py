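"""Round trips and coordinate conventions of the file formats."""

import numpy as np
import pytest

from cryopicker.formats_io import (
    AnnotationSet,
    Micrograph,
    ParticleAnnotation,
    StarRecord,
    build_coco,
    parse_coco,
    read_box_file,
    read_mrc,
    read_star,
    write_box_file,
    write_mrc,
    write_star,
)
from cryopicker.postprocess import ScoredParticle


class TestMrc:
    def test_round_trip_is_bit_identical(self, tmp_path, rng):
        mic = Micrograph(id="m", pixels=rng.normal(size=(64, 64)).astype(np.float32))
        write_mrc(mic, tmp_path / "m.mrc")
        back = read_mrc(tmp_path / "m.mrc")
        assert back.pixels.shape == (64, 64)
        np.testing.assert_array_equal(back.pixels, mic.pixels.astype(np.float64))

    def test_non_square_orientation_preserved(self, tmp_path):
        px = np.zeros((48, 64), dtype=np.float32)
        px[5, 10] = 7.0  # row 5 (y), column 10 (x)
        write_mrc(Micrograph(id="m", pixels=px), tmp_path / "m.mrc")
        back = read_mrc(tmp_path / "m.mrc")
        assert back.pixels.shape == (48, 64)
        assert back.pixels[5, 10] == 7.0
        assert back.pixels.sum() == 7.0

    def test_pixel_size_passthrough(self, tmp_path):
        mic = Micrograph(id="m", pixels=np.zeros((32, 32)), pixel_size=1.06)
        write_mrc(mic, tmp_path / "m.mrc")
        assert read_mrc(tmp_path / "m.mrc").pixel_size == pytest.approx(1.06)

    def test_text_file_rejected(self, tmp_path):
        bad = tmp_path / "fake.mrc"
        bad.write_text("this is not a micrograph")
        with pytest.raises(ValueError, match="MRC"):
            read_mrc(bad)

    def test_volume_rejected(self, tmp_path):
        import gemmi

        vol = gemmi.Ccp4Map()
        vol.grid = gemmi.FloatGrid(np.zeros((16, 16, 8), dtype=np.float32))
        vol.grid.unit_cell = gemmi.UnitCell(16, 16, 8, 90, 90, 90)
        vol.update_ccp4_header()
        vol.write_ccp4_map(str(tmp_path / "vol.mrc"))
        with pytest.raises(ValueError, match="shape"):
            read_mrc(tmp_path / "vol.mrc")


class TestBoxFiles:
    def test_corner_convention(self, tmp_path):
        p = ScoredParticle("m", cx=100, cy=60, bw=40, bh=40, score=0.9)
        write_box_file([p], tmp_path / "m.box", box_size=40)
        assert (tmp_path / "m.box").read_text() == "80\t40\t40\t40\n"

    def test_empty_list_gives_empty_file(self, tmp_path):
        write_box_file([], tmp_path / "e.box", box_size=32)
        assert (tmp_path / "e.box").read_text() == ""

    def test_order_preserved_and_read_back(self, tmp_path):
        parts = [
            ScoredParticle("m", cx=c, cy=c + 1, bw=20, bh=20, score=0.5) for c in (30, 50, 40)
        ]
        write_box_file(parts, tmp_path / "m.box", box_size=20)
        rows = read_box_file(tmp_path / "m.box")
        assert [r[0] for r in rows] == [20, 40, 30]

    def test_mixed_micrographs_rejected(self, tmp_path):
        parts = [
            ScoredParticle("a", 10, 10, 8, 8, 0.5),
            ScoredParticle("b", 10, 10, 8, 8, 0.5),
        ]
        with pytest.raises(ValueError, match="one micrograph"):
            write_box_file(parts, tmp_path / "x.box", box_size=8)

    def test_flip_y_mirrors_vertically(self, tmp_path):
        p = ScoredParticle("m", cx=10, cy=20, bw=8, bh=8, score=0.5)
        write_box_file([p], tmp_path / "m.box", box_size=8, flip_y=100)
        x_min, y_min, _, _ = read_box_file(tmp_path / "m.box")[0]
        assert (x_min, y_min) == (6, 75)  # y -> 99 - 20 = 79, minus half box


class TestStar:
    def test_round_trip_random_records(self, tmp_path, rng):
        records = [
            StarRecord(f"mic_{i % 7}", float(rng.uniform(0, 4000)), float(rng.uniform(0, 4000)),
                       float(np.round(rng.uniform(), 6)))
            for i in range(100)
        ]
        # coordinates at the writer's fixed precision survive exactly
        records = [
            StarRecord(r.micrograph_id, round(r.x, 6), round(r.y, 6), r.score) for r in records
        ]
        write_star(records, tmp_path / "p.star")
        assert read_star(tmp_path / "p.star") == records

    def test_two_micrographs_share_one_loop(self, tmp_path):
        records = [StarRecord("a", 1, 2, 0.5), StarRecord("b", 3, 4, 0.25)]
        write_star(records, tmp_path / "p.star")
        text = (tmp_path / "p.star").read_text()
        assert text.count("loop_") == 1
        assert len([l for l in text.splitlines() if l.startswith(("a", "b"))]) == 2

    def test_empty_list_gives_header_only(self, tmp_path):
        write_star([], tmp_path / "p.star")
        text = (tmp_path / "p.star").read_text()
        assert "loop_" in text and "_rlnCoordinateX" in text
        assert read_star(tmp_path / "p.star") == []

    def test_writer_is_deterministic(self, tmp_path):
        records = [StarRecord("a", 1.5, 2.5, 0.75)]
        write_star(records, tmp_path / "one.star")
        write_star(records, tmp_path / "two.star")
        assert (tmp_path / "one.star").read_bytes() == (tmp_path / "two.star").read_bytes()


class TestCoco:
    def test_counts_and_box_arithmetic(self):
        import json

        aset = AnnotationSet(
            micrographs=[("m1", 100, 200)],
            annotations=[
                ParticleAnnotation(1, "m1", cx=50, cy=50, bw=20, bh=20),
                ParticleAnnotation(2, "m1", cx=80, cy=30, bw=10, bh=10),
            ],
        )
        doc = json.loads(build_coco(aset))
        assert len(doc["images"]) == 1
        assert len(doc["annotations"]) == 2
        assert len(doc["categories"]) == 1
        first = doc["annotations"][0]
        assert first["bbox"] == [40, 40, 20, 20]
        assert first["area"] == 400

    def test_round_trip_many_random_annotations(self, rng):
        mics = [(f"m{i}", 512, 512) for i in range(20)]
        annos = [
            ParticleAnnotation(
                particle_id=i,
                micrograph_id=f"m{int(rng.integers(20))}",
                cx=float(rng.uniform(16, 496)),
                cy=float(rng.uniform(16, 496)),
                bw=float(rng.integers(8, 64)),
                bh=float(rng.integers(8, 64)),
            )
            for i in range(500)
        ]
        aset = AnnotationSet(micrographs=mics, annotations=annos, split_tag="validation")
        back = parse_coco(build_coco(aset))
        assert back.split_tag == "validation"
        assert back.micrographs == mics
        assert back.annotations == annos

    def test_writer_pure_function_of_input(self):
        aset = AnnotationSet(
            micrographs=[("m", 64, 64)],
            annotations=[ParticleAnnotation(1, "m", 32, 32, 16, 16)],
        )
        assert build_coco(aset) == build_coco(aset)

    def test_dangling_micrograph_rejected(self):
        with pytest.raises(ValueError, match="unknown micrograph"):
            AnnotationSet(
                micrographs=[("m", 64, 64)],
                annotations=[ParticleAnnotation(1, "other", 32, 32, 16, 16)],
            )

    def test_duplicate_particle_ids_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            AnnotationSet(
                micrographs=[("m", 64, 64)],
                annotations=[
                    ParticleAnnotation(1, "m", 32, 32, 16, 16),
                    ParticleAnnotation(1, "m", 10, 10, 8, 8),
                ],
            )
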