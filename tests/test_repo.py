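"""Facade behavior: CURIEs, identifier resolution, slicing, snapshots."""

import os

import pytest

from seqvault import Curie, SeqVault
from seqvault.digests import sha512t24u
from seqvault.exceptions import (
    AmbiguousIdentifierError,
    CurieParseError,
    NotFoundError,
    RangeError,
    ReadOnlyError,
)


class TestCurie:
    def test_parse_and_roundtrip(self):
        c = Curie.parse("refseq:NM_0001.1")
        assert (c.prefix, c.reference) == ("refseq", "NM_0001.1")
        assert str(c) == "refseq:NM_0001.1"

    def test_reference_may_contain_colons(self):
        c = Curie.parse("lrg:LRG_1:t1")
        assert c.reference == "LRG_1:t1"

    @pytest.mark.parametrize("bad", ["noprefix", ":ref", "prefix:", ""])
    def test_malformed_curies_are_rejected(self, bad):
        with pytest.raises(CurieParseError):
            Curie.parse(bad)


class TestStoreCounts:
    def test_new_sequence_with_one_identifier(self, writable_repo):
        assert writable_repo.store("ACGTACGT", ["refseq:TEST0"]) == (1, 5)

    def test_repeat_is_fully_redundant(self, writable_repo):
        writable_repo.store("ACGTACGT", ["refseq:TEST0"])
        assert writable_repo.store("ACGTACGT", ["refseq:TEST0"]) == (0, 0)

    def test_new_identifier_for_existing_sequence(self, writable_repo):
        writable_repo.store("ACGTACGT", ["refseq:TEST0"])
        assert writable_repo.store("ACGTACGT", ["ensembl:ENST1"]) == (0, 1)

    def test_malformed_curie_fails_before_any_write(self, writable_repo):
        with pytest.raises(CurieParseError):
            writable_repo.store("ACGTACGT", ["notacurie"])
        assert writable_repo.stats().n_sequences == 0


class TestFetchAndResolution:
    @pytest.fixture(autouse=True)
    def _store(self, writable_repo):
        self.repo = writable_repo
        self.repo.store("ACGTACGT", ["refseq:TEST0"])
        self.repo.commit()
        self.digest = sha512t24u(b"ACGTACGT")

    def test_fetch_by_curie_with_slice(self):
        assert self.repo.fetch("refseq:TEST0", 2, 4) == "GT"
        assert self.repo.fetch("refseq:TEST0") == "ACGTACGT"

    def test_fetch_through_every_computed_identifier(self):
        """Translation closure: all digest CURIEs name the same bytes."""
        for curie in self.repo.translate_identifier("refseq:TEST0"):
            assert self.repo.fetch(curie) == "ACGTACGT"
        assert self.repo.fetch(f"ga4gh:SQ.{self.digest}") == "ACGTACGT"
        assert self.repo.fetch(f"sha512t24u:{self.digest}") == "ACGTACGT"

    def test_bare_alias_when_globally_unique(self):
        assert self.repo.fetch("TEST0") == "ACGTACGT"
        assert self.repo.fetch(self.digest) == "ACGTACGT"

    def test_bare_alias_ambiguity_is_an_error(self):
        self.repo.store("TTTTAAAA", ["other:TEST0"])
        with pytest.raises(AmbiguousIdentifierError) as exc:
            self.repo.fetch("TEST0")
        assert {"refseq", "other"} <= set(exc.value.namespaces)

    def test_unknown_and_bad_range_errors(self):
        with pytest.raises(NotFoundError):
            self.repo.fetch("refseq:ABSENT")
        with pytest.raises(RangeError):
            self.repo.fetch("refseq:TEST0", 5, 2)

    def test_map_style_access_matches_fetch(self):
        proxy = self.repo["refseq:TEST0"]
        assert len(proxy) == 8
        assert proxy[2:4] == self.repo.fetch("refseq:TEST0", 2, 4)
        assert proxy[:] == str(proxy) == "ACGTACGT"
        assert proxy[-2:] == "GT"

    def test_contains_mirrors_resolution(self):
        assert "refseq:TEST0" in self.repo
        assert f"ga4gh:SQ.{self.digest}" in self.repo
        assert "refseq:ABSENT" not in self.repo


class TestTranslateIdentifier:
    def test_target_namespace_filter(self, writable_repo):
        writable_repo.store("ACGTACGT", ["refseq:TEST0"])
        digest = sha512t24u(b"ACGTACGT")
        out = writable_repo.translate_identifier("refseq:TEST0", ["ga4gh"])
        assert [str(c) for c in out] == [f"ga4gh:SQ.{digest}"]
        back = writable_repo.translate_identifier(f"ga4gh:SQ.{digest}")
        assert Curie("refseq", "TEST0") in back
        assert writable_repo.translate_identifier("refseq:TEST0", []) == []

    def test_output_is_sorted_and_round_trips(self, loaded_repo):
        for seq_id in loaded_repo.list_ids():
            curies = loaded_repo.translate_identifier(f"sha512t24u:{seq_id}")
            assert curies == sorted(curies)
            # every emitted CURIE resolves back to the same sequence id
            assert all(loaded_repo._resolve(c) == seq_id for c in curies)


def test_stats_and_list_ids(loaded_repo):
    st = loaded_repo.stats()
    ids = list(loaded_repo.list_ids())
    assert st.n_sequences == len(ids) == len(set(ids)) == 20
    assert st.n_aliases == 20 * 5  # 4 computed + 1 supplied each
    assert st.total_residues == sum(len(loaded_repo[f"sha512t24u:{i}"]) for i in ids)


class TestSnapshot:
    def test_snapshot_serves_identical_content(self, loaded_repo, tmp_path):
        report = loaded_repo.snapshot(tmp_path / "snap")
        snap = SeqVault(tmp_path / "snap")
        assert report.n_files_copied == 2
        for seq_id in loaded_repo.list_ids():
            assert snap.fetch(f"sha512t24u:{seq_id}") == loaded_repo.fetch(
                f"sha512t24u:{seq_id}"
            )
        assert snap.stats() == loaded_repo.stats()
        snap.close()

    def test_volumes_are_hard_linked_not_copied(self, loaded_repo, tmp_path):
        loaded_repo.snapshot(tmp_path / "snap")
        for vol in loaded_repo._fastadir.volumes():
            src = loaded_repo.root / "sequences" / vol.relpath
            dst = tmp_path / "snap" / "sequences" / vol.relpath
            assert os.stat(src).st_nlink == 2
            assert os.stat(src).st_ino == os.stat(dst).st_ino

    def test_snapshot_is_read_only(self, loaded_repo, tmp_path):
        loaded_repo.snapshot(tmp_path / "snap")
        with pytest.raises(ReadOnlyError):
            SeqVault(tmp_path / "snap", writeable=True)
        snap = SeqVault(tmp_path / "snap")
        with pytest.raises(ReadOnlyError):
            snap.store("ACGT")
        snap.close()

    def test_second_snapshot_is_incremental(self, loaded_repo, tmp_path):
        loaded_repo.snapshot(tmp_path / "snap1")
        loaded_repo.store("GATTACAGATTACA", ["test:NEW0"])
        loaded_repo.commit()
        loaded_repo.snapshot(tmp_path / "snap2")
        vols = loaded_repo._fastadir.volumes()
        assert len(vols) == 2
        old_vol, new_vol = vols[0].relpath, vols[1].relpath
        # the old volume now has 3 links (source + both snapshots): no new copy
        src_seq = loaded_repo.root / "sequences"
        assert os.stat(src_seq / old_vol).st_nlink == 3
        assert os.stat(src_seq / new_vol).st_nlink == 2
        assert not (tmp_path / "snap1" / "sequences" / new_vol).exists()
        assert (tmp_path / "snap2" / "sequences" / new_vol).exists()

    def test_non_empty_destination_is_refused(self, loaded_repo, tmp_path):
        dest = tmp_path / "snap"
        dest.mkdir()
        (dest / "junk").write_text("x")
        with pytest.raises(FileExistsError):
            loaded_repo.snapshot(dest)


def test_read_only_open_requires_existing_repo(tmp_path):
    with pytest.raises(NotFoundError):
        SeqVault(tmp_path / "missing")
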