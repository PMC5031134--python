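from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from domarch.annotation_io import (
    ClusterSet,
    DomainHit,
    SourceDB,
    ensure_unique_protein_ids,
    read_cluster_file,
    read_interproscan_tsv,
    restrict_to_annotated,
    write_cluster_file,
)


def tsv_row(protein, analysis, accession, start, end, interpro="-"):
    return "\t".join(
        [protein, "md5", "400", analysis, accession, "desc", str(start), str(end),
         "1.2E-30", "T", "01-01-2016", interpro, "-"]
    )


@pytest.fixture
def two_db_file(tmp_path):
    path = tmp_path / "g1.tsv"
    path.write_text(
        tsv_row("protA", "Pfam", "PF00005", 10, 240) + "\n"
        + tsv_row("protA", "TIGRFAM", "TIGR00001", 300, 380) + "\n"
    )
    return path


class TestReadInterproscan:
    def test_filters_by_database(self, two_db_file):
        ann = read_interproscan_tsv(two_db_file, allowed_dbs={SourceDB.PFAM}, genome_id="g1")
        assert ann.n_hits == 1
        (hit,) = ann.hits["protA"]
        assert (hit.domain_id, hit.start, hit.end) == ("PF00005", 10, 240)

    def test_two_databases_selected(self, two_db_file):
        ann = read_interproscan_tsv(
            two_db_file, allowed_dbs={SourceDB.PFAM, SourceDB.TIGRFAM}, genome_id="g1"
        )
        assert ann.n_hits == 2

    def test_db_names_mapped_case_insensitively(self, two_db_file):
        ann = read_interproscan_tsv(two_db_file, allowed_dbs={"pfam", "TIGRFAMs"}, genome_id="g1")
        assert ann.n_hits == 2

    def test_interpro_column_used_when_selected(self, tmp_path):
        path = tmp_path / "g1.tsv"
        path.write_text(tsv_row("protA", "Pfam", "PF00005", 10, 240, interpro="IPR003439") + "\n")
        ann = read_interproscan_tsv(path, allowed_dbs={SourceDB.INTERPRO}, genome_id="g1")
        assert [h.domain_id for h in ann.hits["protA"]] == ["IPR003439"]

    def test_reversed_coordinates_error_names_line(self, tmp_path):
        path = tmp_path / "g1.tsv"
        path.write_text(
            tsv_row("protA", "Pfam", "PF00005", 10, 240) + "\n"
            + tsv_row("protB", "Pfam", "PF00072", 50, 40) + "\n"
        )
        with pytest.raises(ValueError, match="line 2"):
            read_interproscan_tsv(path, genome_id="g1")

    def test_non_integer_coordinates_error(self, tmp_path):
        path = tmp_path / "g1.tsv"
        path.write_text(tsv_row("protA", "Pfam", "PF00005", "ten", 240) + "\n")
        with pytest.raises(ValueError, match="line 1"):
            read_interproscan_tsv(path, genome_id="g1")

    def test_empty_file_warns(self, tmp_path):
        path = tmp_path / "g1.tsv"
        path.write_text("")
        with pytest.warns(UserWarning, match="no annotation rows"):
            ann = read_interproscan_tsv(path, genome_id="g1")
        assert ann.n_hits == 0

    def test_row_order_irrelevant(self, tmp_path):
        rows = [
            tsv_row("protA", "Pfam", "PF00005", 10, 240),
            tsv_row("protA", "Pfam", "PF00072", 300, 380),
            tsv_row("protB", "Pfam", "PF00106", 5, 90),
        ]
        fwd, rev = tmp_path / "fwd.tsv", tmp_path / "rev.tsv"
        fwd.write_text("\n".join(rows) + "\n")
        rev.write_text("\n".join(reversed(rows)) + "\n")
        a = read_interproscan_tsv(fwd, genome_id="g")
        b = read_interproscan_tsv(rev, genome_id="g")
        assert a.hits == b.hits

    def test_duplicate_hits_retained(self, tmp_path):
        path = tmp_path / "g1.tsv"
        row = tsv_row("protA", "Pfam", "PF00005", 10, 240)
        path.write_text(row + "\n" + row + "\n")
        ann = read_interproscan_tsv(path, genome_id="g1")
        assert len(ann.hits["protA"]) == 2


class TestDomainHit:
    def test_coordinate_invariant(self):
        with pytest.raises(ValueError):
            DomainHit("p", "g", "PF1", SourceDB.PFAM, start=0, end=10)

    def test_separator_rejected_in_domain_id(self):
        with pytest.raises(ValueError, match=";"):
            DomainHit("p", "g", "PF1;PF2", SourceDB.PFAM, start=1, end=10)


class TestClusterFile:
    def test_basic_two_clusters(self, tmp_path):
        path = tmp_path / "c.txt"
        path.write_text("p1 p2\np3\n")
        cs = read_cluster_file(path)
        assert set(cs.clusters.values()) == {frozenset({"p1", "p2"}), frozenset({"p3"})}
        assert cs.universe == {"p1", "p2", "p3"}

    def test_duplicate_membership_is_hard_error(self, tmp_path):
        path = tmp_path / "c.txt"
        path.write_text("p1 p2\np1\n")
        with pytest.raises(ValueError, match="p1"):
            read_cluster_file(path)

    def test_empty_file(self, tmp_path):
        path = tmp_path / "c.txt"
        path.write_text("")
        cs = read_cluster_file(path)
        assert cs.n_clusters == 0 and cs.universe == frozenset()

    def test_blank_lines_ignored(self, tmp_path):
        path = tmp_path / "c.txt"
        path.write_text("p1 p2\n\n\np3\n")
        assert read_cluster_file(path).n_clusters == 2

    @given(
        raw=st.lists(
            st.lists(st.integers(0, 500), min_size=1, max_size=8, unique=True),
            min_size=0,
            max_size=30,
        )
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_write_read_round_trip(self, raw, tmp_path_factory):
        # rename ints to unique protein ids across clusters
        seen: set[str] = set()
        clusters = {}
        for i, members in enumerate(raw):
            fresh = {f"c{i}_{m}" for m in members}
            clusters[f"k{i}"] = frozenset(fresh)
            seen |= fresh
        cs = ClusterSet(label="SB", clusters=clusters)
        path = tmp_path_factory.mktemp("rt") / "c.txt"
        write_cluster_file(cs, path)
        assert read_cluster_file(path) == cs


class TestRestrictToAnnotated:
    @pytest.fixture
    def clusters(self):
        return ClusterSet(
            label="SB",
            clusters={"a": frozenset({"p1", "p2"}), "b": frozenset({"p3"})},
        )

    def test_drops_unannotated_and_empty_clusters(self, clusters):
        out = restrict_to_annotated(clusters, {"p1", "p3"})
        assert set(out.clusters.values()) == {frozenset({"p1"}), frozenset({"p3"})}

    def test_identity_when_all_annotated(self, clusters):
        assert restrict_to_annotated(clusters, {"p1", "p2", "p3", "p9"}) == clusters

    def test_empty_when_disjoint(self, clusters):
        assert restrict_to_annotated(clusters, {"x"}).n_clusters == 0

    def test_idempotent(self, clusters):
        once = restrict_to_annotated(clusters, {"p1", "p3"})
        twice = restrict_to_annotated(once, {"p1", "p3"})
        assert once == twice


def test_protein_id_collision_gets_genome_prefix(tmp_path):
    from domarch.annotation_io import GenomeAnnotation

    def ann(gid):
        hit = DomainHit("prot1", gid, "PF00005", SourceDB.PFAM, 1, 50)
        return GenomeAnnotation(genome_id=gid, hits={"prot1": [hit]})

    fixed = ensure_unique_protein_ids({"g1": ann("g1"), "g2": ann("g2")})
    assert set(fixed["g1"].hits) == {"g1|prot1"}
    assert set(fixed["g2"].hits) == {"g2|prot1"}
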