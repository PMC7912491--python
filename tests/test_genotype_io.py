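"""PLINK text parsing, QC cascade, HWE exact test, dataset construction."""

import numpy as np
import pandas as pd
import pytest

from buffroh import (
    GenotypeError,
    QCParams,
    apply_qc,
    build_datasets,
    hwe_exact_p,
    read_plink_text,
    write_plink_text,
)
from conftest import make_matrix, oracle_hwe


def _write_inputs(tmp_path, ped_lines, map_lines, sheet_rows):
    ped = tmp_path / "toy.ped"
    mp = tmp_path / "toy.map"
    sheet = tmp_path / "toy.samples.tsv"
    ped.write_text("\n".join(ped_lines) + "\n")
    mp.write_text("\n".join(map_lines) + "\n")
    sheet.write_text(
        "sample_id\ttype\tpopulation\n"
        + "\n".join("\t".join(r) for r in sheet_rows)
        + "\n"
    )
    return ped, mp, sheet


class TestReadPlinkText:
    def test_toy_transcription_and_missing(self, tmp_path):
        """2 samples x 3 SNPs: dosages match hand-read alleles; '0 0' is missing."""
        ped, mp, sheet = _write_inputs(
            tmp_path,
            ["F a1 0 0 0 -9 A A A C C C", "F a2 0 0 0 -9 A C 0 0 A A"],
            ["1 s1 0 100", "1 s2 0 200", "1 s3 0 300"],
            [("a1", "river", "P1"), ("a2", "swamp", "P2")],
        )
        gm = read_plink_text(ped, mp, sheet)
        assert gm.calls.tolist() == [[0, 1, 2], [1, -1, 0]]
        assert gm.snps["allele_a"].tolist() == ["A", "A", "A"]
        # SNP 3 only shows C and A across samples -> alleles sorted A, C
        assert gm.snps["allele_b"].tolist() == ["C", "C", "C"]
        assert gm.samples["buffalo_type"].tolist() == ["river", "swamp"]

    def test_shuffled_map_is_sorted_with_calls(self, tmp_path):
        """Out-of-order map: output sorted, call columns permuted identically."""
        ped, mp, sheet = _write_inputs(
            tmp_path,
            ["F a1 0 0 0 -9 A A C C A C G G"],
            ["2 sB 0 500", "1 sA 0 900", "1 sC 0 100", "2 sD 0 50"],
            [("a1", "river", "P1")],
        )
        gm = read_plink_text(ped, mp, sheet)
        assert gm.snps["snp_id"].tolist() == ["sC", "sA", "sD", "sB"]
        assert gm.snps["position_bp"].tolist() == [100, 900, 50, 500]
        # brute-force re-lookup by snp_id against the unsorted transcription
        # (monomorphic SNPs code as dosage 0 of the absent second allele)
        by_id = {"sB": 0, "sA": 0, "sC": 1, "sD": 0}
        got = dict(zip(gm.snps["snp_id"], gm.calls[0]))
        assert got == by_id

    def test_roundtrip(self, tmp_path):
        rng = np.random.default_rng(3)
        calls = rng.choice([-1, 0, 1, 2], size=(4, 12)).astype(np.int8)
        calls[0] = 0  # anchor both alleles in every column so labels survive
        calls[1] = 2
        gm = make_matrix(
            calls,
            positions=list(range(100, 1300, 100)),
            chromosomes=[1] * 6 + [2] * 6,
            types=["river", "river", "swamp", "swamp"],
        )
        ped, mp, sheet = write_plink_text(gm, tmp_path / "rt")
        gm2 = read_plink_text(ped, mp, sheet)
        np.testing.assert_array_equal(gm.calls, gm2.calls)
        assert gm.snps["position_bp"].tolist() == gm2.snps["position_bp"].tolist()

    def test_malformed_line_names_line_number(self, tmp_path):
        ped, mp, sheet = _write_inputs(
            tmp_path,
            ["F a1 0 0 0 -9 A A", "F a2 0 0 0 -9 A"],
            ["1 s1 0 100"],
            [("a1", "river", "P1"), ("a2", "river", "P1")],
        )
        with pytest.raises(GenotypeError, match=":2"):
            read_plink_text(ped, mp, sheet)

    def test_unknown_sample_rejected(self, tmp_path):
        ped, mp, sheet = _write_inputs(
            tmp_path,
            ["F ghost 0 0 0 -9 A A"],
            ["1 s1 0 100"],
            [("a1", "river", "P1")],
        )
        with pytest.raises(GenotypeError, match="ghost"):
            read_plink_text(ped, mp, sheet)

    def test_non_autosomes_dropped(self, tmp_path):
        ped, mp, sheet = _write_inputs(
            tmp_path,
            ["F a1 0 0 0 -9 A A C C"],
            ["1 s1 0 100", "25 sX 0 200"],
            [("a1", "river", "P1")],
        )
        gm = read_plink_text(ped, mp, sheet)
        assert gm.snps["snp_id"].tolist() == ["s1"]


class TestHweExact:
    def test_monomorphic_is_one(self):
        assert hwe_exact_p(10, 0, 0) == 1.0

    def test_small_counts_match_enumeration(self):
        assert hwe_exact_p(3, 5, 2) == pytest.approx(oracle_hwe(3, 5, 2), abs=1e-12)

    def test_all_het_extreme_is_discarded_at_study_threshold(self):
        p = hwe_exact_p(0, 50, 0)
        assert p == pytest.approx(oracle_hwe(0, 50, 0), abs=1e-12)
        assert p < 1e-5

    @pytest.mark.parametrize("seed", range(5))
    def test_random_counts_match_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(40):
            n = int(rng.integers(1, 200))
            counts = rng.multinomial(n, [0.3, 0.4, 0.3])
            a, b, c = map(int, counts)
            assert hwe_exact_p(a, b, c) == pytest.approx(oracle_hwe(a, b, c), abs=1e-12)


class TestApplyQc:
    def test_low_call_rate_sample_removed(self):
        # sample 0: 94/100 called -> below the 0.95 threshold
        calls = np.ones((3, 100), dtype=np.int8)
        calls[0, :6] = -1
        gm = make_matrix(calls, positions=list(range(100, 10100, 100)))
        out, report = apply_qc(gm, QCParams(min_maf=0.0))
        assert report.n_samples_removed == 1
        assert out.samples["sample_id"].tolist() == ["ind1", "ind2"]

    def test_good_snp_retained(self):
        calls = np.array([[0, 0], [1, 2], [2, 2], [1, 0]], dtype=np.int8)
        gm = make_matrix(calls, positions=[100, 200])
        out, _ = apply_qc(gm)
        assert out.n_snps == 2

    def test_filters_match_per_column_oracle(self):
        rng = np.random.default_rng(11)
        n, m = 10, 40
        calls = rng.choice([0, 1, 2], size=(n, m)).astype(np.int8)
        calls[:, 1] = 0   # monomorphic -> MAF 0 < 0.01
        calls[:6, 3] = -1  # 40% SNP call rate (sample call rates stay >= 0.95)
        gm = make_matrix(calls, positions=list(range(100, 100 * (m + 1), 100)))
        out, report = apply_qc(gm)
        assert report.n_samples_removed == 0

        keep_expected = []
        for j in range(m):
            col = calls[:, j]
            called = col[col != -1]
            cr = len(called) / n
            p = called.sum() / (2 * len(called))
            keep_expected.append(cr >= 0.95 and min(p, 1 - p) >= 0.01)
        assert out.snps["snp_id"].tolist() == [
            f"s{j}" for j in range(m) if keep_expected[j]
        ]
        assert report.n_snps_removed == m - sum(keep_expected)

    def test_qc_is_idempotent(self):
        rng = np.random.default_rng(5)
        calls = rng.choice([-1, 0, 1, 2], size=(20, 30), p=[0.02, 0.4, 0.2, 0.38])
        gm = make_matrix(calls.astype(np.int8), positions=list(range(100, 3100, 100)))
        once, _ = apply_qc(gm)
        twice, report = apply_qc(once)
        assert report.n_samples_removed == 0
        assert report.n_snps_removed == 0
        np.testing.assert_array_equal(once.calls, twice.calls)

    def test_all_removed_raises(self):
        calls = np.full((2, 2), -1, dtype=np.int8)
        gm = make_matrix(calls, positions=[100, 200])
        with pytest.raises(GenotypeError, match="empty dataset"):
            apply_qc(gm)


class TestBuildDatasets:
    @staticmethod
    def _panel(seed=2, swamp_mono_cols=(0,)):
        rng = np.random.default_rng(seed)
        n_riv, n_swa, m = 12, 12, 30
        calls = rng.choice([0, 1, 2], size=(n_riv + n_swa, m), p=[0.36, 0.48, 0.16]).astype(np.int8)
        for j in swamp_mono_cols:
            calls[n_riv:, j] = 0
            calls[:4, j] = [1, 1, 2, 2]  # polymorphic in river
        return make_matrix(
            calls,
            positions=list(range(1000, 1000 + 1000 * m, 1000)),
            types=["river"] * n_riv + ["swamp"] * n_swa,
        )

    def test_swamp_monomorphic_excluded_from_all_data_only(self):
        gm = self._panel()
        ds = build_datasets(gm)
        assert "s0" not in set(ds["ALL_DATA"].snps["snp_id"])
        assert "s0" in set(ds["RIVER_DATA"].snps["snp_id"])

    def test_fully_polymorphic_snp_everywhere(self):
        gm = self._panel(swamp_mono_cols=())
        ds = build_datasets(gm)
        for name in ("ALL_DATA", "RIVER_DATA", "SWAMP_DATA"):
            assert "s5" in set(ds[name].snps["snp_id"])

    def test_samples_partition_by_type(self):
        ds = build_datasets(self._panel())
        all_ids = set(ds["ALL_DATA"].samples["sample_id"])
        riv = set(ds["RIVER_DATA"].samples["sample_id"])
        swa = set(ds["SWAMP_DATA"].samples["sample_id"])
        assert riv | swa == all_ids
        assert not riv & swa

    def test_monomorphic_fraction_scales_all_data(self):
        """With 30% of SNPs forced swamp-monomorphic (and negligible drift),
        ALL_DATA keeps ~70% of the post-QC panel."""
        from buffroh import PopulationSpec, SimConfig, simulate_panel

        cfg = SimConfig(
            seed=77,
            n_chromosomes=4,
            snps_per_chromosome=1200,
            populations=(
                PopulationSpec("R", "river", 30, 0.02),
                PopulationSpec("S", "swamp", 30, 0.02),
            ),
            type_divergence=(("river", 0.02), ("swamp", 0.02)),
            swamp_monomorphic_fraction=0.30,
            islands=(),
            roh_rate=(("river", 0.0), ("swamp", 0.0)),
        )
        gm, _ = simulate_panel(cfg)
        gm_qc, _ = apply_qc(gm)
        ds = build_datasets(gm_qc)
        # direct count of swamp-polymorphic columns post-QC
        swamp_maf = gm_qc.maf(sample_mask=gm_qc.type_mask("swamp"))
        assert ds["ALL_DATA"].n_snps == int((swamp_maf > 0).sum())
        frac = ds["ALL_DATA"].n_snps / gm_qc.n_snps
        assert frac == pytest.approx(0.70, abs=0.04)
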