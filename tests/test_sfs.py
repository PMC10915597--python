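import gzip

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from refugia.engine import SampleConfig, simulate_snp_dataset
from refugia.sfs import (
    GenotypeTable,
    JointSFS,
    build_joint_sfs,
    project_site,
    read_fasta_alignment,
    read_pop_map,
    read_sfs,
    read_vcf,
    select_one_snp_per_locus,
    write_sfs,
    write_vcf,
)


@pytest.fixture(scope="module")
def small_table(catalog, null_params):
    return simulate_snp_dataset(catalog["I"], null_params, 60,
                                SampleConfig(6, 4, 4), 0.15, 99)


def _random_table(rng, n_sites=40, n_dip=6, missing=0.2, snps_per_locus=1):
    geno = rng.integers(0, 2, size=(n_sites, n_dip, 2)).astype(np.int8)
    # ensure polymorphism
    geno[:, 0, 0] = 0
    geno[:, -1, -1] = 1
    miss = rng.random((n_sites, n_dip)) < missing
    geno[miss] = -1
    loci = np.array([f"uce-{1 + i // snps_per_locus:04d}"
                     for i in range(n_sites)], dtype=object)
    pops = np.array(["A", "A", "B", "B", "C", "C"][:n_dip])
    return GenotypeTable(
        genotypes=geno,
        site_locus=loci,
        site_pos=np.arange(1, n_sites + 1, dtype=np.int64),
        ref=np.array(["A"] * n_sites, dtype=object),
        alt=np.array(["G"] * n_sites, dtype=object),
        ancestral_known=np.ones(n_sites, dtype=bool),
        samples=[f"s{i}" for i in range(n_dip)],
        sample_pop=pops,
    )


class TestVcfRoundTrip:
    def test_simulated_table_round_trips(self, small_table, tmp_path):
        vcf = tmp_path / "t.vcf"
        write_vcf(small_table, vcf)
        pop_map = {s: p for s, p in zip(small_table.samples,
                                        small_table.sample_pop)}
        back = read_vcf(vcf, pop_map)
        assert np.array_equal(back.genotypes, small_table.genotypes)
        assert list(back.site_locus) == list(small_table.site_locus)
        assert back.samples == small_table.samples
        assert np.all(back.ancestral_known)

    def test_alt_ancestral_is_polarised(self, small_table, tmp_path):
        # flip REF/ALT on one site but keep AA: reader must re-polarise
        vcf = tmp_path / "t.vcf"
        write_vcf(small_table, vcf)
        lines = vcf.read_text().splitlines()
        hdr = [i for i, l in enumerate(lines) if not l.startswith("#")][0]
        parts = lines[hdr].split("\t")
        ref, alt = parts[3], parts[4]
        parts[3], parts[4] = alt, ref
        parts[7] = f"AA={ref}"
        parts[9:] = [
            g.replace("0", "x").replace("1", "0").replace("x", "1")
            for g in parts[9:]]
        lines[hdr] = "\t".join(parts)
        vcf.write_text("\n".join(lines) + "\n")
        pop_map = {s: p for s, p in zip(small_table.samples,
                                        small_table.sample_pop)}
        back = read_vcf(vcf, pop_map)
        assert np.array_equal(
            np.sort(back.genotypes[0].ravel()),
            np.sort(small_table.genotypes[0].ravel()))

    def test_unknown_sample_rejected(self, small_table, tmp_path):
        vcf = tmp_path / "t.vcf"
        write_vcf(small_table, vcf)
        with pytest.raises(ValueError, match="absent from population map"):
            read_vcf(vcf, {small_table.samples[0]: "A"})

    def test_indel_and_multiallelic_skipped(self, tmp_path):
        vcf = tmp_path / "m.vcf"
        header = ("##fileformat=VCFv4.2\n"
                  '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
                  "##contig=<ID=uce-1>\n"
                  "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\n")
        rows = [
            "uce-1\t5\t.\tA\tG\t.\tPASS\t.\tGT\t0/1\t0/0",
            "uce-1\t9\t.\tA\tAT\t.\tPASS\t.\tGT\t0/1\t0/0",   # indel
            "uce-1\t12\t.\tA\tG,T\t.\tPASS\t.\tGT\t0/1\t0/2",  # multiallelic
            "uce-1\t20\t.\tC\tT\t.\tPASS\t.\tGT\t./.\t1/1",
        ]
        vcf.write_text(header + "\n".join(rows) + "\n")
        table = read_vcf(vcf, {"s1": "A", "s2": "B"})
        assert table.n_sites == 2
        assert table.genotypes[1, 0, 0] == -1

    def test_empty_vcf_warns(self, tmp_path):
        vcf = tmp_path / "e.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n")
        with pytest.warns(UserWarning, match="no biallelic"):
            table = read_vcf(vcf, {"s1": "A"})
        assert table.n_sites == 0

    def test_pop_map_parsing(self, tmp_path):
        pm = tmp_path / "pm.tsv"
        pm.write_text("# comment\ns1\tA\ns2\tC\n")
        assert read_pop_map(pm) == {"s1": "A", "s2": "C"}
        pm.write_text("s1\tD\n")
        with pytest.raises(ValueError, match="unknown population"):
            read_pop_map(pm)


class TestOneSnpPerLocus:
    def test_counts(self, rng):
        table = _random_table(rng, n_sites=30, snps_per_locus=3)
        out = select_one_snp_per_locus(table, 5)
        assert out.n_sites == 10
        assert len(set(out.site_locus)) == 10

    def test_idempotent(self, rng):
        table = _random_table(rng, n_sites=30, snps_per_locus=3)
        once = select_one_snp_per_locus(table, 5)
        twice = select_one_snp_per_locus(once, 6)
        assert np.array_equal(once.genotypes, twice.genotypes)

    def test_choice_is_uniform(self, rng):
        table = _random_table(rng, n_sites=3000, missing=0, snps_per_locus=3)
        out = select_one_snp_per_locus(table, 17)
        pos_in_locus = (out.site_pos - 1) % 3
        freq = np.bincount(pos_in_locus, minlength=3) / 1000
        se = np.sqrt((1 / 3) * (2 / 3) / 1000)
        assert np.all(np.abs(freq - 1 / 3) < 3 * se)

    def test_deterministic(self, rng):
        table = _random_table(rng, n_sites=30, snps_per_locus=3)
        a = select_one_snp_per_locus(table, 5)
        b = select_one_snp_per_locus(table, 5)
        assert np.array_equal(a.site_pos, b.site_pos)


class TestProjection:
    def test_exact_small_case(self):
        # direct enumeration: C(2,j) C(2,2-j) / C(4,2)
        np.testing.assert_allclose(project_site(2, 4, 2),
                                   [1 / 6, 4 / 6, 1 / 6], atol=1e-12)

    def test_all_derived_concentrates(self):
        v = project_site(5, 5, 3)
        assert v[-1] == pytest.approx(1.0)

    def test_identity_projection(self):
        v = project_site(3, 7, 7)
        assert v[3] == pytest.approx(1.0)

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            project_site(5, 4, 2)
        with pytest.raises(ValueError):
            project_site(1, 4, 5)

    @settings(deadline=None, derandomize=True)
    @given(st.integers(2, 16).flatmap(
        lambda n: st.tuples(st.just(n), st.integers(0, n),
                            st.integers(1, n))))
    def test_projection_is_unbiased_and_normalised(self, inm):
        n, i, m = inm
        v = project_site(i, n, m)
        assert v.sum() == pytest.approx(1.0, abs=1e-10)
        # E[j]/m = i/n
        assert (v * np.arange(m + 1)).sum() / m == pytest.approx(
            i / n, abs=1e-10)


class TestJointSFS:
    def test_identity_tabulation_without_missing(self, rng):
        table = _random_table(rng, missing=0.0)
        sfs = build_joint_sfs(table, projection_sizes=(4, 4, 4))
        # direct tabulation oracle
        expect = np.zeros((5, 5, 5))
        for s in range(table.n_sites):
            idx = tuple(int((table.haplotypes(p)[s] == 1).sum())
                        for p in "ABC")
            if sum(idx) in (0, 12):
                continue
            expect[idx] += 1
        assert np.allclose(sfs.counts, expect)

    def test_conservation_with_missing(self, rng):
        table = _random_table(rng, n_sites=200, missing=0.25)
        sfs = build_joint_sfs(table)
        total = sfs.total + sum(sfs.dropped.values())
        assert total == pytest.approx(table.n_sites, abs=1e-9)

    def test_all_fixed_sites_dropped(self, rng):
        table = _random_table(rng, missing=0.0)
        table.genotypes[:] = 1
        sfs = build_joint_sfs(table, projection_sizes=(4, 4, 4))
        assert sfs.total == 0
        assert sfs.dropped["monomorphic"] == pytest.approx(table.n_sites)

    def test_projection_exceeding_coverage_rejected(self, rng):
        table = _random_table(rng, missing=0.0)
        with pytest.raises(ValueError, match="exceeds"):
            build_joint_sfs(table, projection_sizes=(5, 4, 4))

    def test_unpolarised_sites_force_folding(self, rng):
        table = _random_table(rng, missing=0.0)
        table.ancestral_known[3] = False
        with pytest.warns(UserWarning, match="folding"):
            sfs = build_joint_sfs(table, projection_sizes=(4, 4, 4))
        assert sfs.folded

    def test_folding_idempotent_and_mass_preserving(self, rng):
        table = _random_table(rng, n_sites=120, missing=0.1)
        sfs = build_joint_sfs(table)
        f1 = sfs.fold()
        f2 = f1.fold()
        assert f1.folded
        assert np.allclose(f1.counts, f2.counts)
        assert f1.total == pytest.approx(sfs.total)
        # no mass on major-allele configurations
        mA, mB, mC = f1.sizes
        iA, iB, iC = np.meshgrid(*(np.arange(m + 1) for m in f1.sizes),
                                 indexing="ij")
        major = (iA + iB + iC) * 2 > (mA + mB + mC)
        assert f1.counts[major].sum() == 0


class TestSfsSerialisation:
    def test_round_trip(self, rng, tmp_path):
        table = _random_table(rng, n_sites=100, missing=0.1)
        sfs = build_joint_sfs(table)
        path = tmp_path / "x.sfs.gz"
        write_sfs(sfs, path)
        back = read_sfs(path)
        assert back.sizes == tuple(sfs.sizes)
        assert back.folded == sfs.folded
        assert np.allclose(back.counts, sfs.counts)
        assert back.dropped == pytest.approx(sfs.dropped)

    def test_hand_written_file(self, tmp_path):
        path = tmp_path / "h.sfs.gz"
        body = ("#refugia-sfs v1\n#sizes: 2 2 2\n#folded: 0\n"
                "#n_input_sites: 3.0\n#dropped_monomorphic: 1.0\n"
                "#dropped_low_coverage: 0.0\n"
                "iA\tiB\tiC\tcount\n1\t0\t0\t1.5\n0\t1\t1\t0.5\n")
        with gzip.open(path, "wt") as fh:
            fh.write(body)
        sfs = read_sfs(path)
        assert sfs.counts[1, 0, 0] == 1.5
        assert sfs.counts[0, 1, 1] == 0.5
        assert sfs.total == 2.0

    def test_corrupted_gzip_raises(self, tmp_path):
        path = tmp_path / "c.sfs.gz"
        path.write_bytes(b"\x1f\x8b\x08\x00garbage-not-gzip")
        with pytest.raises(ValueError, match="cannot read|not a refugia"):
            read_sfs(path)

    def test_shape_mismatch_raises(self, tmp_path):
        path = tmp_path / "s.sfs.gz"
        body = ("#refugia-sfs v1\n#sizes: 2 2 2\n#folded: 0\n"
                "#n_input_sites: 1.0\n#dropped_monomorphic: 0.0\n"
                "#dropped_low_coverage: 0.0\n"
                "iA\tiB\tiC\tcount\n5\t0\t0\t1.0\n")
        with gzip.open(path, "wt") as fh:
            fh.write(body)
        with pytest.raises(ValueError, match="outside shape"):
            read_sfs(path)


class TestFastaReader:
    def test_basic_matrix(self, tmp_path):
        fa = tmp_path / "a.fasta"
        fa.write_text(">s1\nACGTACGTAC\n>s2\nACGTACGTAG\n>s3\nACNTACRTAG\n")
        names, mat = read_fasta_alignment(fa)
        assert names == ["s1", "s2", "s3"]
        assert mat.shape == (3, 10)
        # ambiguity and N are masked
        assert mat[2, 2] == "N" and mat[2, 6] == "N"

    def test_ragged_alignment_rejected(self, tmp_path):
        fa = tmp_path / "r.fasta"
        fa.write_text(">s1\nACGT\n>s2\nACG\n")
        with pytest.raises(ValueError, match="ragged"):
            read_fasta_alignment(fa)

    def test_empty_file_rejected(self, tmp_path):
        fa = tmp_path / "e.fasta"
        fa.write_text("")
        with pytest.raises(ValueError, match="no sequences"):
            read_fasta_alignment(fa)


class TestExternalFormatCheck:
    def test_vcf_parses_with_bcftools(self, small_table, tmp_path):
        import shutil
        import subprocess

        if shutil.which("bcftools") is None:
            pytest.skip("bcftools not on PATH")
        vcf = tmp_path / "t.vcf"
        write_vcf(small_table, vcf)
        res = subprocess.run(["bcftools", "view", "-H", str(vcf)],
                             capture_output=True, text=True, check=True)
        assert len(res.stdout.splitlines()) == small_table.n_sites
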