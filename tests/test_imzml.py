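import hashlib
import io
import re
import warnings

import numpy as np
import pytest

from ramzml import (BinaryIndex, ChecksumMismatch, ChecksumWarning,
                    DimensionMismatch, GridMapping, OffsetOutOfBounds,
                    RamanMap, UnknownDialect, build_binary_index, convert,
                    read_binary_index, read_imzml, validate, write_ibd,
                    write_imzml_xml, write_pair, write_renishaw_text,
                    write_witec_text)

from conftest import make_map


def simulate_layout(n_pixels, n_channels, mode):
    """Independent brute-force layout oracle: append arrays one at a time."""
    cursor = 16
    positions = []

    def append(n_values):
        nonlocal cursor
        off = cursor
        cursor += 4 * n_values
        return off

    if mode == "continuous":
        shared = append(n_channels)
        for _ in range(n_pixels):
            positions.append((shared, append(n_channels)))
    else:
        for _ in range(n_pixels):
            a = append(n_channels)
            positions.append((a, append(n_channels)))
    return positions, cursor


class TestBinaryIndex:
    def test_continuous_layout_four_pixels_three_channels(self):
        m = make_map(width=4, height=1, n_channels=3)
        idx = build_binary_index(m, "continuous", uuid=b"\0" * 16)
        assert all(e.axis_offset == 16 for e in idx.entries)
        assert all(e.axis_encoded_length == 12 for e in idx.entries)
        assert [e.intensity_offset for e in idx.entries] == [28, 40, 52, 64]
        assert idx.total_size == 76

    def test_processed_layout_interleaves_axis_and_intensity(self):
        m = make_map(width=4, height=1, n_channels=3)
        idx = build_binary_index(m, "processed", uuid=b"\0" * 16)
        assert (idx.entries[0].axis_offset, idx.entries[0].intensity_offset) == (16, 28)
        assert (idx.entries[1].axis_offset, idx.entries[1].intensity_offset) == (40, 52)
        assert idx.total_size == 112

    def test_single_value_degenerate_case(self):
        m = make_map(width=1, height=1, n_channels=1)
        idx = build_binary_index(m, "continuous", uuid=b"\0" * 16)
        e = idx.entries[0]
        assert (e.axis_offset, e.axis_encoded_length) == (16, 4)
        assert (e.intensity_offset, e.intensity_encoded_length) == (20, 4)
        assert idx.total_size == 24

    @pytest.mark.parametrize("mode", ["continuous", "processed"])
    def test_matches_brute_force_simulator(self, mode):
        rng = np.random.default_rng(42)
        for _ in range(50):
            w, h = rng.integers(1, 6, 2)
            n_ch = int(rng.integers(1, 17))
            m = make_map(int(w), int(h), n_ch, seed=int(rng.integers(2**16)))
            idx = build_binary_index(m, mode, uuid=b"\0" * 16)
            expected, total = simulate_layout(m.n_pixels, n_ch, mode)
            got = [(e.axis_offset, e.intensity_offset) for e in idx.entries]
            assert got == expected
            assert idx.total_size == total

    @pytest.mark.parametrize("mode", ["continuous", "processed"])
    def test_encoded_length_conservation(self, mode):
        m = make_map(width=3, height=5, n_channels=7)
        idx = build_binary_index(m, mode, uuid=b"\0" * 16)
        intensity_bytes = sum(e.intensity_encoded_length for e in idx.entries)
        if mode == "continuous":
            axis_bytes = idx.entries[0].axis_encoded_length  # stored once
        else:
            axis_bytes = sum(e.axis_encoded_length for e in idx.entries)
        assert 16 + axis_bytes + intensity_bytes == idx.total_size


class TestWriteIbd:
    def test_sha1_of_minimal_zero_file(self):
        # frozen from an independent digest tool: sha1 of 24 zero bytes
        m = RamanMap(axis=[0.0], pixels=[[1, 1]], intensities=[[0.0]])
        idx = build_binary_index(m, "continuous", uuid=b"\0" * 16)
        sha1, n = write_ibd(m, idx, buf := io.BytesIO())
        assert n == 24 and buf.getvalue() == b"\0" * 24
        assert sha1 == "d3399b7262fb56cb9ed053d68db9291c410839c4"

    def test_values_encoded_little_endian_float32(self):
        m = RamanMap(axis=[1.0], pixels=[[1, 1]], intensities=[[2.0]])
        idx = build_binary_index(m, "continuous", uuid=b"\0" * 16)
        _, _ = write_ibd(m, idx, buf := io.BytesIO())
        data = buf.getvalue()
        assert data[20:24] == bytes.fromhex("00000040")  # IEEE-754 single 2.0

    def test_byte_count_equals_index_total(self, tiny_map):
        idx = build_binary_index(tiny_map, "continuous", uuid=b"\0" * 16)
        sha1, n = write_ibd(tiny_map, idx, buf := io.BytesIO())
        assert n == idx.total_size == len(buf.getvalue())
        assert sha1 == hashlib.sha1(buf.getvalue()).hexdigest()


class TestXmlWriter:
    def test_positions_and_count_in_document(self, tmp_path):
        m = make_map(width=2, height=1, n_channels=3)
        pair, _ = write_pair(m, tmp_path / "m", uuid=b"\1" * 16)
        xml = (tmp_path / "m.imzML").read_text()
        assert 'count="2"' in xml
        offsets = re.findall(r'accession="IMS:1000102"[^/]*value="(\d+)"', xml)
        assert offsets[0::2] == ["16", "16"]  # shared continuous axis

    def test_xml_reparses_to_equal_index(self, tmp_path, tiny_map):
        for mode in ("continuous", "processed"):
            idx = build_binary_index(tiny_map, mode, uuid=b"\2" * 16)
            sha1, _ = write_ibd(tiny_map, idx, tmp_path / f"{mode}.ibd")
            write_imzml_xml(tiny_map, idx, sha1, str(tmp_path / f"{mode}.imzML"))
            assert read_binary_index(tmp_path / f"{mode}.imzML") == idx


class TestRoundTrip:
    @pytest.mark.parametrize("mode", ["continuous", "processed"])
    def test_read_after_write_is_identity(self, tmp_path, mode):
        m = make_map(width=3, height=4, n_channels=9, seed=7)
        pair, report = write_pair(m, tmp_path / "rt", mode=mode)
        recovered = read_imzml(pair.xml_path, pair.ibd_path)
        assert recovered == m
        assert report.n_pixels == 12 and report.n_channels == 9
        # stage step survives via the pixel-size scan-settings terms
        assert (recovered.grid.step_x, recovered.grid.step_y) == (2.0, 2.0)

    def test_sparse_map_round_trips(self, tmp_path, sparse_map):
        pair, _ = write_pair(sparse_map, tmp_path / "sp")
        m = read_imzml(pair.xml_path, pair.ibd_path)
        assert m == sparse_map and m.n_pixels == 3

    def test_modes_reconstruct_identical_maps(self, tmp_path, tiny_map):
        a, _ = write_pair(tiny_map, tmp_path / "a", mode="continuous")
        b, _ = write_pair(tiny_map, tmp_path / "b", mode="processed")
        assert read_imzml(a.xml_path, a.ibd_path) == read_imzml(b.xml_path, b.ibd_path)

    def test_fixed_uuid_makes_ibd_bit_identical(self, tmp_path, tiny_map):
        u = bytes(range(16))
        p1, _ = write_pair(tiny_map, tmp_path / "one", uuid=u)
        p2, _ = write_pair(tiny_map, tmp_path / "two", uuid=u)
        b1 = (tmp_path / "one.ibd").read_bytes()
        assert b1 == (tmp_path / "two.ibd").read_bytes()
        assert b1[:16] == u and p1.sha1 == p2.sha1

    def test_truncated_ibd_raises_offset_error(self, tmp_path, tiny_map):
        pair, _ = write_pair(tiny_map, tmp_path / "tr")
        data = (tmp_path / "tr.ibd").read_bytes()
        (tmp_path / "tr.ibd").write_bytes(data[:-4])
        with pytest.raises(OffsetOutOfBounds):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", ChecksumWarning)
                read_imzml(pair.xml_path, pair.ibd_path)

    def test_checksum_mismatch_warns_then_raises_in_strict(self, tmp_path, tiny_map):
        pair, _ = write_pair(tiny_map, tmp_path / "ck")
        data = bytearray((tmp_path / "ck.ibd").read_bytes())
        data[-1] ^= 0xFF
        (tmp_path / "ck.ibd").write_bytes(bytes(data))
        with pytest.warns(ChecksumWarning):
            read_imzml(pair.xml_path, pair.ibd_path)
        with pytest.raises(ChecksumMismatch):
            read_imzml(pair.xml_path, pair.ibd_path, strict_checksum=True)


class TestValidate:
    def test_fresh_pair_has_no_findings(self, tmp_path, tiny_map):
        pair, _ = write_pair(tiny_map, tmp_path / "ok")
        assert validate(pair.xml_path, pair.ibd_path).ok

    def test_flipped_payload_byte_is_exactly_a_checksum_finding(self, tmp_path, tiny_map):
        pair, _ = write_pair(tiny_map, tmp_path / "fl")
        original = (tmp_path / "fl.ibd").read_bytes()
        # every payload byte, one at a time
        for pos in range(16, len(original)):
            data = bytearray(original)
            data[pos] ^= 0x01
            (tmp_path / "fl.ibd").write_bytes(bytes(data))
            assert validate(pair.xml_path, pair.ibd_path).codes() == [
                "CHECKSUM_MISMATCH"]

    def test_flipped_header_byte_also_breaks_uuid(self, tmp_path, tiny_map):
        pair, _ = write_pair(tiny_map, tmp_path / "hd")
        data = bytearray((tmp_path / "hd.ibd").read_bytes())
        data[0] ^= 0x01
        (tmp_path / "hd.ibd").write_bytes(bytes(data))
        codes = validate(pair.xml_path, pair.ibd_path).codes()
        assert set(codes) == {"UUID_MISMATCH", "CHECKSUM_MISMATCH"}

    def test_truncation_yields_offset_finding(self, tmp_path, tiny_map):
        pair, _ = write_pair(tiny_map, tmp_path / "tr")
        data = (tmp_path / "tr.ibd").read_bytes()
        (tmp_path / "tr.ibd").write_bytes(data[:-4])
        assert "OFFSET_OUT_OF_BOUNDS" in validate(pair.xml_path,
                                                  pair.ibd_path).codes()

    def test_inconsistent_encoded_length_detected(self, tmp_path, tiny_map):
        pair, _ = write_pair(tiny_map, tmp_path / "enc")
        xml = (tmp_path / "enc.imzML").read_text()
        enc = tiny_map.n_channels * 4
        xml = xml.replace(
            f'accession="IMS:1000104" name="external encoded length" value="{enc}"',
            f'accession="IMS:1000104" name="external encoded length" value="{enc + 1}"',
            1)
        (tmp_path / "enc.imzML").write_text(xml)
        assert "ENCODED_LENGTH_INCONSISTENT" in validate(
            pair.xml_path, pair.ibd_path).codes()

    def test_duplicated_mode_term_detected(self, tmp_path, tiny_map):
        pair, _ = write_pair(tiny_map, tmp_path / "md")
        xml = (tmp_path / "md.imzML").read_text()
        term = '<cvParam cvRef="IMS" accession="IMS:1000030" name="continuous" value="" />'
        xml = xml.replace(term, term + term, 1)
        (tmp_path / "md.imzML").write_text(xml)
        assert "MODE_TERM_COUNT" in validate(pair.xml_path, pair.ibd_path).codes()

    def test_garbage_xml_is_a_finding_not_an_exception(self, tmp_path, tiny_map):
        pair, _ = write_pair(tiny_map, tmp_path / "gb")
        (tmp_path / "gb.imzML").write_text("<mzML>not closed")
        assert validate(pair.xml_path, pair.ibd_path).codes() == ["MALFORMED_XML"]


class TestConvert:
    def test_renishaw_fixture_full_pipeline(self, tmp_path, tiny_map):
        write_renishaw_text(tiny_map, tmp_path / "in.txt")
        pair, report = convert(tmp_path / "in.txt", tmp_path / "out")
        assert validate(pair.xml_path, pair.ibd_path).ok
        assert read_imzml(pair.xml_path, pair.ibd_path) == tiny_map
        assert "not" in report.lost_metadata_note  # metadata loss is stated

    def test_witec_requires_dimensions(self, tmp_path, tiny_map):
        write_witec_text(tiny_map, tmp_path / "in.txt")
        with pytest.raises(DimensionMismatch, match="width and.*height"):
            convert(tmp_path / "in.txt", tmp_path / "out", vendor="witec")

    def test_witec_with_dimensions_round_trips(self, tmp_path, tiny_map):
        write_witec_text(tiny_map, tmp_path / "in.txt")
        pair, _ = convert(tmp_path / "in.txt", tmp_path / "out", vendor="witec",
                          witec_width=2, witec_height=2, witec_step=(2.0, 2.0))
        assert read_imzml(pair.xml_path, pair.ibd_path) == tiny_map

    def test_auto_sniff_failure_raises(self, tmp_path):
        (tmp_path / "bad.txt").write_text("no numbers here\n")
        with pytest.raises(UnknownDialect):
            convert(tmp_path / "bad.txt", tmp_path / "out")

    def test_fixed_uuid_is_deterministic(self, tmp_path, tiny_map):
        write_renishaw_text(tiny_map, tmp_path / "in.txt")
        u = "00112233-4455-6677-8899-aabbccddeeff"
        convert(tmp_path / "in.txt", tmp_path / "a", uuid=u)
        convert(tmp_path / "in.txt", tmp_path / "b", uuid=u)
        assert (tmp_path / "a.ibd").read_bytes() == (tmp_path / "b.ibd").read_bytes()
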