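"""Prohormone-processing grammar: signal peptide, cleavage, peptide
derivation, motifs, and the precursor-likeness score."""

import pytest

from bombemine.annotate import (annotate_precursor, derive_peptides,
                                find_cleavage_sites, predict_signal_peptide,
                                scan_motif, score_precursor,
                                segment_precursor, PrecursorAnnotation)
from bombemine.seq_io import SeqRecord
from bombemine.synthetic import make_precursor


class TestSignalPeptide:
    def test_generator_recovery(self):
        hits = 0
        for seed in range(100):
            rec, truth = make_precursor(seed=seed, signal_len=21)
            span = predict_signal_peptide(rec.residues)
            if span is not None and abs(span[1] - truth.signal_span[1]) <= 3:
                hits += 1
        assert hits >= 90

    def test_poly_acidic_n_terminus_rejected(self):
        assert predict_signal_peptide("D" * 40) is None

    def test_no_basic_start_rejected(self):
        assert predict_signal_peptide("MA" + "L" * 20 + "A" + "N" * 20) is None

    def test_override_passthrough(self):
        assert predict_signal_peptide("D" * 40, override=(0, 19)) == (0, 19)

    def test_short_protein(self):
        assert predict_signal_peptide("MKLLLLLLLL") is None


class TestCleavageSites:
    def test_simple_dibasic(self):
        sites = find_cleavage_sites("AAKRWW")
        assert len(sites) == 1
        assert sites[0].position == 3 and sites[0].basic_pair == "KR"

    def test_arbn_internal_rr(self):
        # the Arg pair at positions 2-3 of the mature bombesin-type peptide
        sites = find_cleavage_sites("EPRRNYNRVFGPTY")
        assert [(s.position, s.basic_pair) for s in sites] == [(3, "RR")]

    def test_no_sites(self):
        assert find_cleavage_sites("AAAAAA") == []

    def test_leftmost_greedy_overlap(self):
        sites = find_cleavage_sites("KRR")
        assert [(s.position, s.basic_pair) for s in sites] == [(1, "KR")]

    def test_scan_oracle(self):
        # brute force: every i with pair in set, skipping consumed residues
        protein = "KRAARRKKWRKRAA"
        dibasic = ("KR", "RR", "KK", "RK")
        expected = []
        i = 0
        while i < len(protein) - 1:
            if protein[i:i + 2] in dibasic:
                expected.append(i + 1)
                i += 2
            else:
                i += 1
        got = [s.position for s in find_cleavage_sites(protein, dibasic)]
        assert got == expected

    def test_monobasic_off_by_default(self):
        assert find_cleavage_sites("AAARAAA") == []

    def test_monobasic_isolated_r_only(self):
        sites = find_cleavage_sites("AAARAAKRA", allow_monobasic=True)
        kinds = [(s.kind, s.position) for s in sites]
        assert ("monobasic", 3) in kinds
        # the R of the KR pair is not also a monobasic site
        assert all(k == "monobasic" and p == 3 or k == "dibasic"
                   for k, p in kinds)

    def test_bad_dibasic_set(self):
        with pytest.raises(ValueError):
            find_cleavage_sites("AA", dibasic_set=("KR", "QQ"))


class TestDerivePeptides:
    def _derive(self, protein, **kw):
        return derive_peptides(protein, None, find_cleavage_sites(protein),
                               **kw)

    def test_full_amidated_peptide_with_internal_pair(self):
        # 14-residue amidated product despite the internal Arg pair
        peps = self._derive("M" + "KR" + "EPRRNYNRVFGPTYG" + "KR" + "A")
        amid = [p for p in peps if p.amidated]
        full = [p for p in amid if p.parent_peptide is None]
        assert [p.sequence for p in full] == ["EPRRNYNRVFGPTY"]
        assert len(full[0]) == 14

    def test_internal_truncation_reported_with_parent(self):
        peps = self._derive("M" + "KR" + "EPRRNYNRVFGPTYG" + "KR" + "A")
        trunc = [p for p in peps if p.parent_peptide]
        assert [(p.sequence, len(p), p.amidated) for p in trunc] == \
            [("NYNRVFGPTY", 10, True)]
        assert trunc[0].parent_peptide == "EPRRNYNRVFGPTY"

    def test_pyroglutamate_and_amide_flags(self):
        # amphibian-type peptide: N-terminal Gln cyclizes, C-terminal
        # Gly donates the amide
        prot = "M" + "KR" + "QQRLGNQWAVGHLMG" + "KR" + "A"
        peps = self._derive(prot)
        (pep,) = [p for p in peps if p.amidated]
        assert pep.sequence == "QQRLGNQWAVGHLM"
        assert pep.pyroglutamate and pep.amidated

    def test_sixteen_residue_amidated_product(self):
        prot = "M" + "KR" + "EPMPSSLALYIANLSPG" + "KR" + "AAAAA"
        (pep,) = [p for p in self._derive(prot) if p.amidated]
        assert pep.sequence == "EPMPSSLALYIANLSP" and len(pep) == 16

    def test_site_order_invariance(self):
        prot = "M" + "KR" + "EPRRNYNRVFGPTYG" + "KR" + "A"
        sites = find_cleavage_sites(prot)
        a = derive_peptides(prot, None, sites)
        b = derive_peptides(prot, None, list(reversed(sites)))
        assert [(p.sequence, p.span) for p in a] == \
            [(p.sequence, p.span) for p in b]

    def test_min_max_error(self):
        with pytest.raises(ValueError):
            derive_peptides("AAAA", None, [], min_len=10, max_len=5)

    def test_length_filter_after_g_removal(self):
        # 4-residue segment + G: survives min_len=4 only because G is
        # removed after the check boundary
        prot = "M" + "KR" + "NPTWG" + "KR" + "AAAA"
        peps = self._derive(prot, min_len=4, max_len=40)
        assert any(p.sequence == "NPTW" and p.amidated for p in peps)
        peps5 = self._derive(prot, min_len=5, max_len=40)
        assert not any(p.sequence == "NPTW" for p in peps5)

    def test_reconstruction_from_segments(self):
        rec, _ = make_precursor(seed=3)
        prot = rec.residues
        sites = find_cleavage_sites(prot)
        signal = predict_signal_peptide(prot)
        segments, cuts = segment_precursor(prot, signal, sites)
        pieces = sorted(segments + cuts)
        assert "".join(prot[a:b] for a, b in pieces) == prot


class TestScanMotif:
    def test_c_terminal_gpxxg(self):
        assert scan_motif("EPRRNYNRVFGPTYG", "GPxxG", "C_terminal") == \
            [(10, 15)]

    def test_amide_required_pattern(self):
        assert scan_motif("EPRRNYNRVFGPTY", "FGPxxa", amidated=True) == \
            [(9, 14)]
        assert scan_motif("EPRRNYNRVFGPTY", "FGPxxa", amidated=False) == []

    def test_no_match(self):
        assert scan_motif("AAAA", "WW") == []

    def test_overlapping_matches_reported(self):
        assert scan_motif("ABAB", "xB") == [(0, 2), (2, 4)]

    def test_empty_pattern_rejected(self):
        with pytest.raises(ValueError):
            scan_motif("AAA", "")


class TestScore:
    def test_planted_scores_high(self, planted):
        rec, _ = planted
        assert annotate_precursor(rec).score >= 4.5

    def test_decoy_scores_low(self):
        rec, _ = make_precursor(seed=5, decoy=True)
        assert annotate_precursor(rec).score <= 1.0

    def test_removing_signal_never_raises_score(self, planted):
        rec, _ = planted
        ann = annotate_precursor(rec)
        stripped = PrecursorAnnotation(
            record=ann.record, signal=None, sites=ann.sites,
            peptides=ann.peptides, motif_hits=ann.motif_hits)
        assert score_precursor(stripped) <= ann.score

    def test_planted_beat_decoys_every_seed(self):
        # ranking separation over many independent proteome draws
        from bombemine.synthetic import make_proteome
        from bombemine.pipeline import run_discovery
        for seed in range(10):
            recs, _ = make_proteome(seed=seed, n_planted=3, n_decoys=30)
            tab = run_discovery(recs).ranking_table()
            planted = tab[tab.id.str.startswith("planted")].score
            decoy = tab[tab.id.str.startswith("decoy")].score
            assert planted.min() > decoy.max()
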