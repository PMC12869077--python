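"""Sibling-filtered unique-peptide frequency and intensity fraction."""

import numpy as np
import pytest
from scipy import stats as sps

from conftest import make_report
from mistraq import chem, quantify as qt


def wild_row(i, seq, protein="PROT1", start=1, rep="rep1"):
    return {
        "protein_id": protein,
        "base_sequence": seq,
        "start": start,
        "replicate_id": rep,
        "run_id": f"s_{rep}",
    }


def sub_row(seq, pos, start=1, protein="PROT1", rep="rep1", frm="P", to="S"):
    return {
        "protein_id": protein,
        "base_sequence": seq,
        "modified_sequence": f"{seq}|{frm}{pos}{to}",
        "start": start,
        "sub_pos": pos,
        "sub_from": frm,
        "sub_to": to,
        "replicate_id": rep,
        "run_id": f"s_{rep}",
    }


class TestUniquePeptideFrequency:
    def test_hand_enumerated_example(self):
        # 38 wild-type P-containing peptides + 2 substituted with observed
        # siblings -> 100 * 2 / 40 = 5.0%
        rows = [
            wild_row(i, f"A{'P'}K", protein=f"P{i}") for i in range(38)
        ]
        rows = []
        for i in range(38):
            rows.append(wild_row(i, "APK", protein=f"P{i:02d}"))
        rows.append(sub_row("ASK", 2, protein="P00"))
        rows.append(sub_row("ASK", 2, protein="P01"))
        report = make_report(rows)
        freq = qt.unique_peptide_frequency(report, chem.PRO_TO_SER)
        assert freq == pytest.approx(5.0)

    def test_sibling_filter_removes_orphan(self):
        rows = [wild_row(i, "APK", protein=f"W{i}") for i in range(10)]
        rows.append(sub_row("ASK", 2, protein="ORPHAN"))
        freq = qt.unique_peptide_frequency(make_report(rows), chem.PRO_TO_SER)
        assert freq == 0.0

    def test_no_substituted_peptides(self):
        rows = [wild_row(0, "APK"), wild_row(1, "AKPK", protein="P2")]
        freq = qt.unique_peptide_frequency(make_report(rows), chem.PRO_TO_SER)
        assert freq == 0.0

    def test_empty_denominator_is_nan(self):
        rows = [wild_row(0, "AAK")]
        freq = qt.unique_peptide_frequency(make_report(rows), chem.PRO_TO_SER)
        assert np.isnan(freq)

    def test_duplicate_rows_collapse(self):
        rows = [wild_row(0, "APK"), sub_row("ASK", 2)]
        once = qt.unique_peptide_frequency(make_report(rows), chem.PRO_TO_SER)
        twice = qt.unique_peptide_frequency(
            make_report(rows + rows), chem.PRO_TO_SER
        )
        assert once == twice == pytest.approx(100.0 * 1 / 2)

    def test_monotone_in_accepted_substitutions(self):
        base = [wild_row(i, "APK", protein=f"W{i}") for i in range(5)]
        base += [wild_row(9, "GPAK", protein="W0", start=4)]
        one = base + [sub_row("ASK", 2, protein="W0")]
        two = one + [sub_row("GSAK", 5, start=4, protein="W0")]
        f1 = qt.unique_peptide_frequency(make_report(one), chem.PRO_TO_SER)
        f2 = qt.unique_peptide_frequency(make_report(two), chem.PRO_TO_SER)
        assert f2 >= f1

    def test_codon_restricted_denominator(self):
        from mistraq.codons import CdsRecord, validate_cds

        # P2 of PROT_A encoded by CCA (targeted); P2 of PROT_B by CCG
        cds_index = {
            "PROT_A": validate_cds(CdsRecord("PROT_A", "ATGCCAAAA", "MPK")),
            "PROT_B": validate_cds(CdsRecord("PROT_B", "ATGCCGAAA", "MPK")),
        }
        spec = chem.SubstitutionSpec("P", "S", frozenset({"CCA"}))
        rows = [
            wild_row(0, "MPK", protein="PROT_A"),
            wild_row(1, "MPK", protein="PROT_B"),
        ]
        unrestricted = qt.unique_peptide_frequency(make_report(rows), spec)
        assert unrestricted == 0.0
        rows.append(sub_row("MSK", 2, protein="PROT_A"))
        freq = qt.unique_peptide_frequency(
            make_report(rows), spec, codon_restricted=True, cds_index=cds_index
        )
        # denominator: PROT_A wild peptide (CCA) + the accepted substituted
        assert freq == pytest.approx(100.0 * 1 / 2)


class TestIntensityFraction:
    def test_simple_arithmetic(self):
        rows = [
            dict(wild_row(0, "APK"), intensity=495.0),
            dict(sub_row("ASK", 2), intensity=5.0),
        ]
        result = qt.intensity_fraction(make_report(rows), chem.PRO_TO_SER)
        assert result.per_replicate["rep1"] == pytest.approx(1.0)

    def test_no_substituted_matches(self):
        rows = [dict(wild_row(0, "APK"), intensity=100.0)]
        result = qt.intensity_fraction(make_report(rows), chem.PRO_TO_SER)
        assert result.per_replicate["rep1"] == 0.0

    def test_mean_and_sd_over_replicates(self):
        rows = []
        for rep, (sub_i, total) in {
            "rep1": (0.70, 100.0),
            "rep2": (0.73, 100.0),
            "rep3": (0.76, 100.0),
        }.items():
            rows.append(
                dict(wild_row(0, "APK", rep=rep), intensity=total - sub_i)
            )
            rows.append(dict(sub_row("ASK", 2, rep=rep), intensity=sub_i))
        result = qt.intensity_fraction(make_report(rows), chem.PRO_TO_SER)
        assert result.mean == pytest.approx(0.73)
        assert result.sd == pytest.approx(0.03)

    def test_invariant_under_global_rescaling(self):
        rows = [
            dict(wild_row(0, "APK"), intensity=400.0),
            dict(sub_row("ASK", 2), intensity=4.0),
        ]
        report = make_report(rows)
        scaled = report.assign(intensity=report["intensity"] * 1e3)
        a = qt.intensity_fraction(report, chem.PRO_TO_SER)
        b = qt.intensity_fraction(scaled, chem.PRO_TO_SER)
        assert a.per_replicate == pytest.approx(b.per_replicate)

    def test_zero_total_intensity_flagged(self):
        rows = [dict(wild_row(0, "APK"), intensity=0.0)]
        result = qt.intensity_fraction(make_report(rows), chem.PRO_TO_SER)
        assert np.isnan(result.per_replicate["rep1"])


class TestFrequencyReport:
    def _two_strain_report(self, strain_values, control_values):
        rows = []
        for strain, values in (
            ("mut", strain_values),
            ("EV", control_values),
        ):
            for r, frac in enumerate(values, start=1):
                rep = f"rep{r}"
                rows.append(
                    dict(
                        wild_row(0, "APK", rep=rep),
                        strain_id=strain,
                        intensity=100.0 - frac,
                    )
                )
                rows.append(
                    dict(
                        sub_row("ASK", 2, rep=rep),
                        strain_id=strain,
                        intensity=frac,
                    )
                )
        return make_report(rows)

    def test_clear_separation_is_significant(self):
        report = self._two_strain_report(
            [1.0, 1.05, 0.95, 1.02, 0.98, 1.0], [0.0, 0.01, 0.0, 0.02, 0.01, 0.0]
        )
        estimates = qt.frequency_report(
            report, {"mut": chem.PRO_TO_SER}, "EV"
        )
        mut = next(e for e in estimates if e.strain_id == "mut")
        # single comparison: Bonferroni leaves p unchanged
        assert mut.adj_p_vs_control == pytest.approx(mut.p_vs_control)
        assert mut.adj_p_vs_control < 0.01
        # agreement with a direct t CDF computation
        a = list(mut.per_replicate_intensity.values())
        b = [0.0, 0.01, 0.0, 0.02, 0.01, 0.0]
        t, p = sps.ttest_ind(a, b, equal_var=True)
        assert mut.p_vs_control == pytest.approx(p)

    def test_identical_groups_p_is_one(self):
        report = self._two_strain_report([0.5] * 3, [0.5] * 3)
        estimates = qt.frequency_report(
            report, {"mut": chem.PRO_TO_SER}, "EV"
        )
        mut = next(e for e in estimates if e.strain_id == "mut")
        assert mut.adj_p_vs_control == 1.0

    def test_bonferroni_multiplies_by_comparisons(self):
        report = self._two_strain_report(
            [1.0, 1.1, 0.9], [0.5, 0.6, 0.4]
        )
        extra = report[report["strain_id"] == "mut"].copy()
        frames = [report]
        for name in ("mut2", "mut3"):
            dup = extra.copy()
            dup["strain_id"] = name
            frames.append(dup)
        import pandas as pd

        big = pd.concat(frames, ignore_index=True)
        specs = {
            "mut": chem.PRO_TO_SER,
            "mut2": chem.PRO_TO_SER,
            "mut3": chem.PRO_TO_SER,
        }
        estimates = qt.frequency_report(big, specs, "EV")
        for e in estimates:
            if np.isfinite(e.p_vs_control):
                assert e.adj_p_vs_control == pytest.approx(
                    min(1.0, 3 * e.p_vs_control)
                )

    def test_recovers_simulated_fraction(self, small_result, small_config):
        report = small_result.mistranslation_report
        report = report[report["global_q"] <= 0.01]
        for strain in ("pro_to_ala", "pro_to_ser", "arg_to_ser"):
            spec = small_config.strain(strain).substitution
            target = small_config.strain(strain).intensity_fraction_pct
            frame = report[report["strain_id"] == strain]
            est = qt.intensity_fraction(frame, spec)
            # small ORFeome: allow generous but bounded deviation
            assert est.mean == pytest.approx(target, rel=0.35)
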