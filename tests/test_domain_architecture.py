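"""EF-hand/kinase scanning, pattern matching and architecture typing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from panscan.core_io import ConfigError, ProteinRecord, ValidationError
from panscan.domain_architecture import (
    Architecture,
    DomainHit,
    PS00018,
    PrositePattern,
    build_architecture,
    classify_family,
    cluster_architectures,
    load_external_domains,
    match_pattern,
    scan_ef_hands,
    scan_kinase,
)

AA20 = "ACDEFGHIKLMNPQRSTVWY"

# Independent expansion of the calcium-binding loop pattern into explicit
# per-position residue classes (the brute-force oracle).
_ALL = set(AA20)
ORACLE_CLASSES = [
    {"D"},
    _ALL | {"X"},
    {"D", "N", "S"},
    _ALL - set("ILVFYW"),
    set("DENSTG"),
    set("DNQGHRK"),
    _ALL - set("GP"),
    set("LIVMC"),
    set("DENQSTAGC"),
    _ALL | {"X"},
    _ALL | {"X"},
    {"D", "E"},
    set("LIVMFYW"),
]


def oracle_matches(seq: str) -> list[tuple[int, int]]:
    out = []
    for s in range(len(seq) - 12):
        window = seq[s : s + 13]
        if all(window[i] in ORACLE_CLASSES[i] for i in range(13)):
            out.append((s, s + 13))
    return out


class TestMatchPattern:
    def test_canonical_loop_single_match(self):
        assert match_pattern("DKDGDGTITTKEL", PS00018) == [(0, 13)]

    def test_empty_sequence(self):
        assert match_pattern("", PS00018) == []

    def test_poly_ala_no_match(self):
        assert match_pattern("A" * 13, PS00018) == []

    def test_ambiguity_code_never_satisfies_constrained_position(self):
        assert match_pattern("XKDGDGTITTKEL", PS00018) == []

    def test_unparseable_pattern_rejected(self):
        with pytest.raises(ConfigError):
            PrositePattern.parse("D-[-x", id="bad")

    def test_variable_wildcard_width(self):
        pat = PrositePattern.parse("A-x(1,3)-C", id="v")
        assert match_pattern("ABC", pat) == [(0, 3)]
        assert match_pattern("ABBBC", pat) == [(0, 5)]

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.text(alphabet=AA20 + "X", min_size=0, max_size=400))
    def test_agrees_with_bruteforce_oracle(self, seq):
        assert match_pattern(seq, PS00018) == oracle_matches(seq)

    def test_agrees_with_oracle_on_loop_rich_sequences(self, rng):
        # Random sequences enriched with planted loops so matches occur.
        for _ in range(200):
            n = int(rng.integers(13, 120))
            seq = "".join(AA20[i] for i in rng.integers(0, 20, size=n))
            pos = int(rng.integers(0, n - 12))
            seq = seq[:pos] + "DKDGDGTITTKEL" + seq[pos + 13 :]
            assert match_pattern(seq, PS00018) == oracle_matches(seq)


class TestScanEfHands:
    def test_strict_loop_is_functional(self):
        p = ProteinRecord("p", sequence="GGG" + "DKDGDGTITTKEL" + "GGG")
        (hit,) = scan_ef_hands(p)
        assert hit.ca_site is True
        assert (hit.start, hit.end) == (3, 16)

    def test_position5_violation_is_degenerate(self):
        # Coordinating position 5 flipped to an excluded residue (K).
        loop = "DKDGKGTITTKEL"
        (hit,) = scan_ef_hands(ProteinRecord("p", sequence=loop))
        assert hit.ca_site is False

    def test_three_coordinating_violations_rejected(self):
        # Positions 3, 5 and 9 all violated: no longer an EF-hand.
        loop = "DKAGKGTIKTKEL"
        assert scan_ef_hands(ProteinRecord("p", sequence=loop)) == []

    def test_both_anchors_lost_rejected(self):
        # Positions 1 and 12 violated (two violations but no anchor left).
        loop = "AKDGDGTITTKAL"
        assert scan_ef_hands(ProteinRecord("p", sequence=loop)) == []

    def test_non_overlap_greedy(self):
        seq = "DKDGDGTITTKEL" * 3
        hits = scan_ef_hands(ProteinRecord("p", sequence=seq))
        assert [(h.start, h.end) for h in hits] == [(0, 13), (13, 26), (26, 39)]

    def test_functional_hits_contain_strict_match(self, rng):
        for _ in range(100):
            n = int(rng.integers(20, 200))
            seq = "".join(AA20[i] for i in rng.integers(0, 20, size=n))
            for h in scan_ef_hands(ProteinRecord("p", sequence=seq)):
                window = seq[h.start : h.end]
                if h.ca_site:
                    assert match_pattern(window, PS00018) == [(0, 13)]


class TestScanKinase:
    def _kinase_seq(self, with_dfg=True):
        seq = "M" + "Q" * 20 + "AYIK" + "Q" * 100 + "HRD" + "Q" * 85
        if with_dfg:
            seq += "DFG"
        return seq + "Q" * 20

    def test_complete_kinase(self):
        hit = scan_kinase(ProteinRecord("p", sequence=self._kinase_seq()))
        assert hit is not None and hit.complete

    def test_anchor_subset_incomplete(self):
        hit = scan_kinase(
            ProteinRecord("p", sequence=self._kinase_seq(with_dfg=False))
        )
        assert hit is not None and not hit.complete

    def test_no_anchors(self):
        assert scan_kinase(ProteinRecord("p", sequence="A" * 300)) is None

    def test_anchors_out_of_span_not_complete(self):
        # All three anchors present but spread over far more than the
        # allowed kinase-domain extent.
        seq = "AYIK" + "Q" * 400 + "HRD" + "Q" * 400 + "DFG"
        hit = scan_kinase(ProteinRecord("p", sequence=seq))
        assert hit is not None and not hit.complete


class TestBuildArchitecture:
    def test_canonical_cpk_signature_and_lobes(self):
        hits = [DomainHit("KINASE", 30, 300, complete=True)] + [
            DomainHit("EF_HAND", 320 + 25 * i, 333 + 25 * i, ca_site=True)
            for i in range(4)
        ]
        arch = build_architecture(hits, 450)
        assert arch.signature == "K|E*E*E*E*"
        assert arch.lobes == ("N", "N", "C", "C")

    def test_single_c_lobe_ca_site(self):
        hits = [DomainHit("KINASE", 30, 300, complete=True)] + [
            DomainHit("EF_HAND", 320 + 25 * i, 333 + 25 * i, ca_site=(i == 2))
            for i in range(3)
        ]
        arch = build_architecture(hits, 450)
        assert arch.lobes == ("N", "C", "C")
        assert arch.ef_hands == (False, False, True)

    def test_no_hits_empty_signature(self):
        arch = build_architecture([], 100)
        assert arch.signature == "" and arch.kinase_state == "absent"

    def test_two_kinase_hits_rejected(self):
        hits = [
            DomainHit("KINASE", 0, 200, complete=True),
            DomainHit("KINASE", 250, 400, complete=True),
        ]
        with pytest.raises(ValidationError):
            build_architecture(hits, 500)

    def test_no_lobes_without_kinase(self):
        hits = [
            DomainHit("EF_HAND", 10 + 20 * i, 23 + 20 * i, ca_site=True)
            for i in range(3)
        ]
        assert build_architecture(hits, 100).lobes == ("none",) * 3


class TestLoadExternalDomains:
    def _write(self, tmp_path, rows):
        p = tmp_path / "dom.tsv"
        lines = ["protein_id\tsource_id\tstart\tend"]
        lines += ["\t".join(map(str, r)) for r in rows]
        p.write_text("\n".join(lines) + "\n")
        return p

    def test_ca_site_inside_ef(self, tmp_path):
        p = self._write(tmp_path, [("p1", "PS50222", 10, 40),
                                   ("p1", "PS00018", 12, 24)])
        (hit,) = load_external_domains(p)["p1"]
        assert hit.kind == "EF_HAND" and hit.ca_site

    def test_ef_without_ca_site(self, tmp_path):
        p = self._write(tmp_path, [("p1", "PS50222", 10, 40)])
        (hit,) = load_external_domains(p)["p1"]
        assert hit.ca_site is False

    def test_orphan_ca_site_dropped_with_warning(self, tmp_path):
        p = self._write(tmp_path, [("p1", "PS50222", 150, 190),
                                   ("p1", "PS00018", 200, 212)])
        with pytest.warns(UserWarning, match="dropped"):
            (hit,) = load_external_domains(p)["p1"]
        assert hit.ca_site is False

    def test_near_orphan_attached(self, tmp_path):
        p = self._write(tmp_path, [("p1", "PS50222", 150, 190),
                                   ("p1", "PS00018", 192, 199)])
        with pytest.warns(UserWarning, match="attached"):
            (hit,) = load_external_domains(p)["p1"]
        assert hit.ca_site is True


def _arch(sig_kinase, flags):
    if sig_kinase != "absent" and len(flags) >= 2:
        lobes = tuple("C" if i >= len(flags) - 2 else "N"
                      for i in range(len(flags)))
    else:
        lobes = ("none",) * len(flags)
    return Architecture(kinase_state=sig_kinase, ef_hands=tuple(flags),
                        lobes=lobes)


class TestClusterArchitectures:
    def test_majority_representative(self):
        a = _arch("complete", (True,) * 4)
        b = _arch("complete", (True,) * 3)
        members = [(f"g{i}", a) for i in range(27)] + [
            (f"h{i}", b) for i in range(3)
        ]
        cl = cluster_architectures(members, "CPK1")
        assert cl.representative.signature == "K|E*E*E*E*"
        assert cl.variants[0][0].signature == "K|E*E*E*"

    def test_solo_excluded(self):
        a = _arch("complete", (True,) * 4)
        solo = _arch("complete", (False, True, True, True))
        cl = cluster_architectures(
            [("g1", a), ("g2", a), ("g3", solo)], "CPK1"
        )
        assert [s.signature for s in cl.solo_excluded] == [solo.signature]

    def test_tie_broken_by_ca_count(self):
        a = _arch("complete", (True, True, True, True))
        b = _arch("complete", (True, True, True, False))
        cl = cluster_architectures(
            [("g1", a), ("g2", a), ("g3", b), ("g4", b)], "x"
        )
        assert cl.representative.signature == a.signature

    def test_permutation_invariant(self, rng):
        archs = [
            _arch("complete", (True,) * 4),
            _arch("complete", (True,) * 4),
            _arch("complete", (True,) * 3),
            _arch("complete", (True,) * 3),
            _arch("absent", (True, True)),
        ]
        members = [(f"g{i}", a) for i, a in enumerate(archs)]
        base = cluster_architectures(members, "x")
        for _ in range(10):
            perm = [members[i] for i in rng.permutation(len(members))]
            cl = cluster_architectures(perm, "x")
            assert cl.representative.signature == base.representative.signature
            assert [a.signature for a, _ in cl.variants] == [
                a.signature for a, _ in base.variants
            ]

    def test_all_solo_flagged(self):
        cl = cluster_architectures(
            [("g1", _arch("complete", (True,) * 4)),
             ("g2", _arch("complete", (True,) * 3))],
            "x",
        )
        assert cl.all_solo and cl.representative is None


class TestClassifyFamily:
    def test_identity_hits_own_family(self, default_dataset):
        seeds = default_dataset.genome_set.seeds
        for fam, members in seeds.items():
            label, score, _ = classify_family(members[0], seeds)
            assert label == fam

    def test_empty_seed_set_rejected(self):
        with pytest.raises(ConfigError):
            classify_family(ProteinRecord("p", sequence="MGNACSK"), {})

    def test_kinase_only_cpk_gets_warning(self, default_dataset):
        seeds = default_dataset.genome_set.seeds
        cpk_seed = seeds["CPK"][0]
        arch = _arch("complete", ())
        label, _, warns = classify_family(cpk_seed, seeds, arch)
        assert label == "CPK"
        assert any("EF-hand" in w for w in warns)

    def test_score_floor_yields_none(self, default_dataset):
        seeds = default_dataset.genome_set.seeds
        junk = ProteinRecord("junk", sequence="PG" * 30)
        label, score, _ = classify_family(junk, seeds, score_floor=100.0)
        assert label == "none"
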