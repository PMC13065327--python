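"""Sequence-window extraction, motif matching and logo statistics."""

import re

import numpy as np
import pytest
from hypothesis import given, strategies as st

from baitquant import (
    MotifPattern,
    PhosphoSiteId,
    extract_window,
    load_motif_config,
    match_motif,
    motif_fractions,
    position_probability_matrix,
)
from baitquant.model import AMINO_ACIDS
from baitquant.motifs import SequenceWindow, extract_windows


_counter = iter(range(10**6))


def window(text, k=None):
    """Build a SequenceWindow around the centre of `text`, with a unique
    synthetic site id."""
    if k is None:
        k = len(text) // 2
    centre = text[k]
    return SequenceWindow(
        site=PhosphoSiteId(f"P{next(_counter)}", centre, 1 + k),
        window=text, k=k,
    )


class TestExtractWindow:
    SEQS = {"P1": "ACDEFSHIKLMN"}

    def test_left_padding_near_n_terminus(self):
        """S at position 6 of a 12-mer with k=6: one pad left, the whole
        sequence, and (12-12)=0 pads right -> '_ACDEFSHIKLMN'."""
        w = extract_window(PhosphoSiteId("P1", "S", 6), self.SEQS, k=6)
        assert w.window == "_ACDEFSHIKLMN"
        assert w.residue_at(0) == "S"

    def test_position_one_gets_k_left_pads(self):
        w = extract_window(PhosphoSiteId("P1", "A", 1).__class__("P1", "S", 6),
                           self.SEQS, k=2)
        assert w.window == "EFSHI"
        w1 = extract_window(PhosphoSiteId("P2", "S", 1), {"P2": "SKLM"}, k=3)
        assert w1.window == "___SKLM"

    def test_residue_mismatch_rejected(self):
        with pytest.raises(ValueError, match="FASTA has"):
            extract_window(PhosphoSiteId("P1", "T", 6), self.SEQS, k=3)

    def test_unknown_protein_rejected(self):
        with pytest.raises(KeyError):
            extract_window(PhosphoSiteId("nope", "S", 1), self.SEQS)

    def test_window_length_always_2k_plus_1(self):
        for pos, res in [(1, "A"), (6, "S"), (12, "N")]:
            if res not in "STY":
                continue
            w = extract_window(PhosphoSiteId("P1", res, pos), self.SEQS, k=6)
            assert len(w.window) == 13


class TestMatchMotif:
    polo = MotifPattern("Polo_stringent", {-2: frozenset("DEN"), 1: frozenset("F")})
    cdk = MotifPattern("minimal_Cdk", {1: frozenset("P")})

    def test_polo_stringent_match(self):
        # -2 D, centre S, +1 F
        assert match_motif(window("AAAADASFAAAAA"), self.polo)

    def test_minimal_cdk_proline_plus_one(self):
        assert match_motif(window("AAAAAASPAAAAA"), self.cdk)
        assert not match_motif(window("AAAAAASAAAAAA"), self.cdk)

    def test_centre_defaults_to_st(self):
        assert not match_motif(window("AAAAAAYPAAAAA"), self.cdk)

    def test_padding_never_matches(self):
        w = window("____D_SF_____")
        assert match_motif(w, self.polo)
        edge = window("______SF_____")  # -2 is a pad
        assert not match_motif(edge, self.polo)

    def test_removing_constraint_is_monotone(self):
        """Dropping a constrained position can only grow the match set."""
        rng = np.random.default_rng(10)
        full = MotifPattern("full", {-2: frozenset("DE"), 1: frozenset("F"),
                                     3: frozenset("KR")})
        relaxed = MotifPattern("relaxed", {-2: frozenset("DE"),
                                           1: frozenset("F")})
        for _ in range(300):
            chars = rng.choice(list(AMINO_ACIDS), 13)
            chars[6] = rng.choice(list("ST"))
            w = window("".join(chars))
            if match_motif(w, full):
                assert match_motif(w, relaxed)

    def test_position_outside_window_rejected(self):
        wide = MotifPattern("wide", {9: frozenset("A")})
        with pytest.raises(ValueError, match="outside"):
            match_motif(window("AAASAAA"), wide)


def regex_for(pattern, k):
    """Independent oracle: compile the motif to a character-class regex
    over the full window string ('_' excluded from every class)."""
    parts = []
    for pos in range(-k, k + 1):
        allowed = pattern.constraints.get(pos)
        parts.append("[" + "".join(sorted(allowed)) + "]" if allowed else ".")
    return re.compile("^" + "".join(parts) + "$")


class TestRegexOracle:
    def test_matcher_equals_regex_oracle_on_random_windows(self):
        """10^4 random +/-6 windows x all default patterns."""
        rng = np.random.default_rng(99)
        patterns = load_motif_config()
        k = 6
        oracles = {p.name: regex_for(p, k) for p in patterns}
        alphabet = np.array(list(AMINO_ACIDS + "_"))
        centres = np.array(list("STY"))
        for _ in range(10_000 // 20):
            for _ in range(20):
                chars = alphabet[rng.integers(0, len(alphabet), 2 * k + 1)]
                chars[k] = centres[rng.integers(0, 3)]
                w = window("".join(chars), k=k)
                for p in patterns:
                    assert match_motif(w, p) == bool(
                        oracles[p.name].match(w.window)
                    ), (w.window, p.name)


class TestMotifFractions:
    def test_percent_arithmetic(self):
        cdk = MotifPattern("minimal_Cdk", {1: frozenset("P")})
        windows = [window("ASP", k=1), window("ASA", k=1),
                   window("GTA", k=1), window("CSD", k=1)]
        out = motif_fractions(windows, [cdk])
        assert out.iloc[0]["percent"] == pytest.approx(25.0)
        assert out.iloc[0]["n_sites"] == 4

    def test_unconstrained_pattern_matches_all_st_centres(self):
        vacuous = MotifPattern("any", {})
        windows = [window("ASP", k=1), window("GTA", k=1)]
        out = motif_fractions(windows, [vacuous])
        assert out.iloc[0]["percent"] == 100.0

    def test_empty_stratum_reported_undefined(self):
        cdk = MotifPattern("minimal_Cdk", {1: frozenset("P")})
        w = window("ASP", k=1)
        out = motif_fractions([w], [cdk],
                              strata={w.site.format(): (), "ghost": ("late",)})
        late = out[out["stratum"] == "late"].iloc[0]
        assert late["n_sites"] == 0 and np.isnan(late["percent"])

    def test_stratified_denominators(self):
        cdk = MotifPattern("minimal_Cdk", {1: frozenset("P")})
        w1, w2, w3 = (window("ASP", k=1), window("ASA", k=1),
                      window("CSP", k=1))
        strata = {
            w1.site.format(): ("early",),
            w2.site.format(): ("early", "late"),
            w3.site.format(): ("late",),
        }
        # strata keys collide because all three share site P-S-2; rebuild
        windows = []
        strata = {}
        for i, (text, labs) in enumerate(
            [("ASP", ("early",)), ("ASA", ("early", "late")),
             ("CSP", ("late",))]
        ):
            w = SequenceWindow(PhosphoSiteId(f"Q{i}", "S", 2), text, 1)
            windows.append(w)
            strata[w.site.format()] = labs
        out = motif_fractions(windows, [cdk], strata)
        early = out[out["stratum"] == "early"].iloc[0]
        late = out[out["stratum"] == "late"].iloc[0]
        assert early["n_sites"] == 2 and early["percent"] == 50.0
        assert late["n_sites"] == 2 and late["percent"] == 50.0


class TestPPM:
    def test_hand_counts(self):
        """Windows {ASP, TSP}: -1 splits A/T at 0.5, 0 is all S, +1 all P."""
        windows = [window("ASP", k=1), window("TSP", k=1)]
        ppm = position_probability_matrix(windows, k=1)
        assert ppm.loc[-1, "A"] == 0.5 and ppm.loc[-1, "T"] == 0.5
        assert ppm.loc[0, "S"] == 1.0
        assert ppm.loc[1, "P"] == 1.0

    def test_single_window_one_hot(self):
        ppm = position_probability_matrix([window("ASP", k=1)], k=1)
        assert (ppm.max(axis=1) == 1.0).all()

    def test_rows_sum_to_one_random_sets(self):
        rng = np.random.default_rng(23)
        alphabet = np.array(list(AMINO_ACIDS))
        for _ in range(20):
            ws = []
            for _ in range(rng.integers(1, 15)):
                chars = alphabet[rng.integers(0, 20, 9)]
                chars[4] = "S"
                ws.append(window("".join(chars), k=4))
            ppm = position_probability_matrix(ws, k=4)
            np.testing.assert_allclose(ppm.sum(axis=1), 1.0)

    def test_pad_only_positions_are_zero(self):
        ppm = position_probability_matrix([window("__S__", k=2)], k=2)
        assert ppm.loc[-2].sum() == 0.0
        assert ppm.loc[0, "S"] == 1.0

    def test_permutation_invariant(self):
        ws = [window("ASP", k=1), window("TSC", k=1), window("GSD", k=1)]
        a = position_probability_matrix(ws, k=1)
        b = position_probability_matrix(ws[::-1], k=1)
        assert a.equals(b)


class TestMotifConfig:
    def test_default_set_loads(self):
        patterns = {p.name: p for p in load_motif_config()}
        assert patterns["Polo_stringent"].constraints[-2] == frozenset("DEN")
        assert patterns["Polo_stringent"].constraints[1] == frozenset("F")
        assert patterns["minimal_Cdk"].constraints[1] == frozenset("P")
        # position-0 default injected everywhere
        for p in patterns.values():
            assert p.constraints[0] == frozenset("ST")

    def test_custom_config_overrides(self, tmp_path):
        cfg = tmp_path / "motifs.yaml"
        cfg.write_text("MyKinase:\n  -3: R\n  0: STY\n")
        (p,) = load_motif_config(cfg)
        assert p.constraints == {-3: frozenset("R"), 0: frozenset("STY")}

    def test_empty_residue_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            MotifPattern("bad", {1: frozenset()})


class TestMotifSiteHeatmap:
    def test_toy_join_matches_hand_assembly(self, caplog):
        import logging

        import pandas as pd

        from baitquant.model import AnnotationTable
        from baitquant.motifs import motif_site_heatmap_table
        from baitquant import PhosphoMatrix
        from conftest import make_design

        design = make_design(conditions=("c1", "c2"), n_replicates=2,
                             tags=("tag",))
        cols = design.select(fraction="PE")
        df = pd.DataFrame(
            [[2.0, 4.0, 6.0, 8.0],   # Ndc80-S-7 matches (+1 P)
             [1.0, 1.0, 1.0, 1.0],   # Ndc80-S-12 does not
             [5.0, 5.0, 5.0, 5.0]],  # Bg1-S-3 matches but not kinetochore
            index=["Ndc80-S-7", "Ndc80-S-12", "Bg1-S-3"], columns=cols,
        )
        phospho = PhosphoMatrix(df, "protein_normalized")
        seqs = {"Ndc80": "AAAAAASPAAASAAA", "Bg1": "AASPAA"}
        windows = extract_windows(phospho.sites, seqs, k=2)
        annotation = AnnotationTable.from_mapping(
            {"Ndc80": ("KMN", True), "Bg1": ("other", False)})
        cdk = MotifPattern("minimal_Cdk", {1: frozenset("P")})
        out = motif_site_heatmap_table(phospho, windows, cdk, annotation,
                                       design)
        assert list(out.index) == ["Ndc80-S-7"]
        assert out.loc["Ndc80-S-7", "c1"] == 3.0  # mean of 2 and 4
        assert out.loc["Ndc80-S-7", "c2"] == 7.0
        assert out.loc["Ndc80-S-7", "subcomplex"] == "KMN"

        # empty match set: empty table plus a warning
        never = MotifPattern("never", {1: frozenset("W"), -1: frozenset("W")})
        with caplog.at_level(logging.WARNING):
            empty = motif_site_heatmap_table(phospho, windows, never,
                                             annotation, design)
        assert empty.empty and "no kinetochore sites" in caplog.text
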