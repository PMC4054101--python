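import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phosresp import (
    PhosphoSiteAnnotation,
    build_window,
    load_motif_library,
    match_motif,
    motif_viability_correlation,
    parse_motif,
)
from phosresp.motifs import AMINO_ACIDS, CENTER, PAD, SequenceWindow, WINDOW_LENGTH
from phosresp.markers import correlate_peptides
from phosresp import drug_response_config, default_viability_table
from phosresp import generate_drug_response_dataset, generate_protein_db_and_sites
from phosresp import full_normalize
from conftest import make_normalized


def window(chars: str, peptide_id="pep") -> SequenceWindow:
    return SequenceWindow(peptide_id=peptide_id, window=chars)


class TestParseMotif:
    def test_offsets_located_relative_to_acceptor(self):
        m = parse_motif("xRxxSx", "xRxxSx", "ST")
        assert m.offsets == {-3: "R"}
        m2 = parse_motif("RxRxxSx", "RxRxxSx", "ST")
        assert m2.offsets == {-5: "R", -3: "R"}

    def test_two_acceptor_candidates_rejected(self):
        with pytest.raises(ValueError, match="acceptor"):
            parse_motif("SxS", "SxS", "ST")

    def test_lowercase_mark_disambiguates(self):
        m = parse_motif("SxS_marked", "sxS", "ST")
        assert m.offsets == {2: "S"}

    def test_illegal_character_rejected(self):
        with pytest.raises(ValueError, match="illegal"):
            parse_motif("bad", "xBxSx", "ST")

    def test_subset_relation(self):
        lib = {m.name: m for m in load_motif_library()}
        assert lib["xRxxSx"].is_subset_of(lib["RxRxxSx"])
        assert lib["xRxxSx"].is_subset_of(lib["KxRxxSx"])
        assert not lib["RxRxxSx"].is_subset_of(lib["xRxxSx"])


class TestBuildWindow:
    PROTEINS = {"P1": "MAAAAAAASAAAAAAA", "P2": "SAAAAAAAAAT"}

    def test_interior_site_no_padding(self):
        w = build_window(PhosphoSiteAnnotation("pep", "P1", 9, "S"), self.PROTEINS)
        assert w.window == "AAAAAAASAAAAAAA"
        assert w.center_residue == "S"

    def test_n_terminal_site_padded(self):
        w = build_window(PhosphoSiteAnnotation("pep", "P2", 1, "S"), self.PROTEINS)
        assert w.window.startswith(PAD * 7)
        assert w.window[CENTER] == "S"

    def test_c_terminal_site_padded(self):
        w = build_window(PhosphoSiteAnnotation("pep", "P2", 11, "T"), self.PROTEINS)
        assert w.window.endswith(PAD * 7)

    def test_near_terminal_padding_count(self):
        # site at protein position 4 needs exactly 4 leading pads
        proteins = {"P": "AAAS" + "A" * 20}
        w = build_window(PhosphoSiteAnnotation("pep", "P", 4, "S"), proteins)
        assert w.window[:4] == PAD * 4 and w.window[4] == "A"

    def test_residue_mismatch_and_missing_protein(self):
        with pytest.raises(ValueError, match="mismatch"):
            build_window(PhosphoSiteAnnotation("pep", "P1", 2, "S"), self.PROTEINS)
        with pytest.raises(KeyError, match="P9"):
            build_window(PhosphoSiteAnnotation("pep", "P9", 1, "S"), self.PROTEINS)


class TestMatchMotif:
    def test_named_basophilic_motif(self):
        m = parse_motif("xRxxSx", "xRxxSx", "ST")
        assert match_motif(window("AAAARAASAAAAAAA"), m)
        assert match_motif(window("AAAARAATAAAAAAA"), m)  # S/T merged
        assert not match_motif(window("AAAAAAASAAAAAAA"), m)
        assert not match_motif(window("AAAARAAYAAAAAAA"), m)  # wrong center class

    def test_all_wildcard_st_motif_matches_any_st_center(self):
        m = parse_motif("any", "S", "ST")
        assert match_motif(window("AAAAAAATAAAAAAA"), m)
        assert not match_motif(window("AAAAAAAYAAAAAAA"), m)

    def test_padding_never_satisfies_constraint_but_matches_wildcard(self):
        m = parse_motif("xRxxSx", "xRxxSx", "ST")
        assert not match_motif(window("____AAASAAAAAAA"), m)  # R position padded
        assert match_motif(window("_AAARAASAAAAAAA"), m)

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_constraint_subset_implication(self, seed):
        # a window matching the stricter motif always matches the looser one
        rng = np.random.default_rng(seed)
        chars = rng.choice(list(AMINO_ACIDS), size=WINDOW_LENGTH)
        chars[CENTER] = rng.choice(["S", "T", "Y"])
        w = window("".join(chars))
        lib = load_motif_library()
        by_name = {m.name: m for m in lib}
        for strict, loose in [("RxRxxSx", "xRxxSx"), ("KxRxxSx", "xRxxSx")]:
            if match_motif(w, by_name[strict]):
                assert match_motif(w, by_name[loose])


class TestLibrary:
    def test_packaged_library_contains_named_basophilic_motifs(self):
        names = {m.name for m in load_motif_library()}
        assert {"xRxSx", "xKxSx", "xRxxSx", "RxRxxSx", "KxRxxSx"} <= names

    def test_custom_library_parses_and_errors_carry_line_numbers(self, tmp_path):
        ok = tmp_path / "lib.tsv"
        ok.write_text("name\tpattern\tclass\nm1\txSPx\tST\nm2\tY\tY\nm3\tSxxE\tST\n")
        assert len(load_motif_library(ok)) == 3
        bad = tmp_path / "bad.tsv"
        bad.write_text("name\tpattern\tclass\nm1\txSPx\tST\nm2\tSxS\tST\n")
        with pytest.raises(ValueError, match="line 3"):
            load_motif_library(bad)

    def test_duplicate_names_rejected(self, tmp_path):
        dup = tmp_path / "dup.tsv"
        dup.write_text("name\tpattern\tclass\nm1\txSPx\tST\nm1\tY\tY\n")
        with pytest.raises(ValueError, match="duplicate"):
            load_motif_library(dup)


class TestMotifCorrelation:
    def _setup(self):
        import pandas as pd
        from phosresp import SampleMeta, ViabilityTable
        rows, cols = [], []
        viabs = [10.0, 30.0, 50.0, 70.0, 90.0]
        for i, v in enumerate(viabs):
            rows.append({"sample_id": f"L{i}_r0", "cell_line": f"L{i}",
                         "disease": "AML", "replicate": 0})
            cols.append(f"L{i}_r0")
        meta = SampleMeta(pd.DataFrame(rows).set_index("sample_id"))
        viab = ViabilityTable(pd.DataFrame(
            {"cell_line": [f"L{i}" for i in range(5)], "drug": "d",
             "viability_percent": viabs}))
        return meta, viab, cols, np.asarray(viabs)

    def test_single_matching_peptide_motif_r_equals_peptide_r(self):
        meta, viab, cols, viabs = self._setup()
        vals = np.vstack([np.exp(0.02 * viabs), np.exp(-0.01 * viabs)])
        normm = make_normalized(vals, peptides=["a", "b"], samples=cols)
        windows = {"a": window("AAAARAASAAAAAAA", "a"), "b": window("AAAAAAAYAAAAAAA", "b")}
        lib = [parse_motif("xRxxSx", "xRxxSx", "ST"), parse_motif("pY", "Y", "Y")]
        res = motif_viability_correlation(windows, normm, meta, viab, "d", lib,
                                          r_peptide_threshold=None)
        rec = correlate_peptides(normm, meta, viab, "d").set_index("peptide_id")
        tab = res.table.set_index("motif")
        assert tab.at["xRxxSx", "r_log"] == pytest.approx(rec.at["a", "r_log"], abs=1e-12)
        assert tab.at["pY", "r_log"] == pytest.approx(rec.at["b", "r_log"], abs=1e-12)
        assert tab.at["xRxxSx", "n_matched"] == 1

    def test_zero_match_motifs_listed_separately(self):
        meta, viab, cols, viabs = self._setup()
        normm = make_normalized(np.exp(0.02 * viabs)[None, :], peptides=["a"], samples=cols)
        windows = {"a": window("AAAAAAASAAAAAAA", "a")}
        lib = [parse_motif("pY", "Y", "Y"), parse_motif("any", "S", "ST")]
        res = motif_viability_correlation(windows, normm, meta, viab, "d", lib,
                                          r_peptide_threshold=None)
        assert res.unmatched == ("pY",)
        assert list(res.table["motif"]) == ["any"]

    def test_duplicate_peptide_rows_collapse(self):
        import pandas as pd
        meta, viab, cols, viabs = self._setup()
        vals = np.exp(0.02 * viabs)
        df = pd.DataFrame([vals, vals * 2, np.exp(-0.02 * viabs)],
                          index=["a", "a", "b"], columns=cols)
        from phosresp.preprocess import NormalizedMatrix
        dup = NormalizedMatrix(df)
        single = make_normalized(np.vstack([vals, np.exp(-0.02 * viabs)]),
                                 peptides=["a", "b"], samples=cols)
        windows = {"a": window("AAAARAASAAAAAAA", "a"), "b": window("AAAARAATAAAAAAA", "b")}
        lib = [parse_motif("xRxxSx", "xRxxSx", "ST")]
        r_dup = motif_viability_correlation(windows, dup, meta, viab, "d", lib,
                                            r_peptide_threshold=None)
        r_single = motif_viability_correlation(windows, single, meta, viab, "d", lib,
                                               r_peptide_threshold=None)
        assert r_dup.table.at[0, "r_log"] == pytest.approx(
            r_single.table.at[0, "r_log"], abs=1e-12)

    def test_ranking_invariant_to_sample_and_peptide_order(self):
        meta, viab, cols, viabs = self._setup()
        rng = np.random.default_rng(0)
        vals = np.vstack([np.exp(0.02 * viabs), rng.lognormal(size=5),
                          np.exp(-0.015 * viabs)])
        peps = ["a", "b", "c"]
        windows = {"a": window("AAAARAASAAAAAAA", "a"),
                   "b": window("AAAAAAASPAAAAAA", "b"),
                   "c": window("AAAAAAAYAAAAAAA", "c")}
        lib = [parse_motif("xRxxSx", "xRxxSx", "ST"), parse_motif("xSPx", "xSPx", "ST"),
               parse_motif("pY", "Y", "Y")]
        base = motif_viability_correlation(
            windows, make_normalized(vals, peptides=peps, samples=cols),
            meta, viab, "d", lib, r_peptide_threshold=None)
        perm = [2, 0, 1]
        shuffled = make_normalized(vals[perm][:, ::-1],
                                   peptides=[peps[i] for i in perm],
                                   samples=cols[::-1])
        other = motif_viability_correlation(windows, shuffled, meta, viab, "d", lib,
                                            r_peptide_threshold=None)
        assert list(base.table["motif"]) == list(other.table["motif"])


class TestSyntheticProteinDb:
    def test_windows_realize_assigned_motifs(self):
        cfg = drug_response_config(n_peptides=120, peptides_per_motif=8, seed=3)
        viab = default_viability_table([line for line, _ in cfg.cell_lines], seed=3)
        ds = generate_drug_response_dataset(cfg, viab)
        proteins, sites = generate_protein_db_and_sites(cfg, ds.truth.motif_assignments)
        lib = {m.name: m for m in load_motif_library()}
        windows = {s.peptide_id: build_window(s, proteins) for s in sites}
        for pep, motif_name in ds.truth.motif_assignments.items():
            assert match_motif(windows[pep], lib[motif_name]), (pep, motif_name)

    def test_unassigned_peptides_get_valid_sty_centers(self):
        cfg = drug_response_config(n_peptides=40, assigned_motifs=(), seed=4)
        proteins, sites = generate_protein_db_and_sites(cfg, {})
        for s in sites:
            w = build_window(s, proteins)
            assert w.center_residue in "STY"

    def test_deterministic(self):
        cfg = drug_response_config(n_peptides=30, seed=5)
        a = generate_protein_db_and_sites(cfg, {"pep0001": "xSPx"})
        b = generate_protein_db_and_sites(cfg, {"pep0001": "xSPx"})
        assert a[0] == b[0]
        assert [(s.peptide_id, s.position, s.residue) for s in a[1]] == [
            (s.peptide_id, s.position, s.residue) for s in b[1]]

    def test_missing_assignments_rejected(self):
        cfg = drug_response_config(n_peptides=10, seed=6)
        with pytest.raises(ValueError, match="motif_assignments"):
            generate_protein_db_and_sites(cfg)
        with pytest.raises(ValueError, match="missing from the library"):
            generate_protein_db_and_sites(cfg, {"pep0001": "not_a_motif"})


def test_planted_responsive_motif_ranks_first():
    cfg = drug_response_config(seed=12, n_peptides=800, peptides_per_motif=10)
    viab = default_viability_table([line for line, _ in cfg.cell_lines], seed=12)
    ds = generate_drug_response_dataset(cfg, viab)
    normm = full_normalize(ds.intensities)
    proteins, sites = generate_protein_db_and_sites(cfg, ds.truth.motif_assignments)
    windows = {s.peptide_id: build_window(s, proteins) for s in sites}
    res = motif_viability_correlation(windows, normm, ds.meta, ds.viability,
                                      ds.truth.marker_drug)
    assert res.table.iloc[0]["motif"] == ds.truth.responsive_motif
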