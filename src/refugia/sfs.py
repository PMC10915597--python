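"""Genotype tables, SNP filters and joint site-frequency spectra.

Reads biallelic SNPs from VCF (via cyvcf2) with a two-column population map,
applies the one-random-SNP-per-locus filter, and builds joint SFS over the
three population clusters.  Missing genotypes are handled by *expected
hypergeometric projection*: each site contributes its exact projection
distribution to cells at fixed projected sample sizes, so a site with a few
uncalled copies still contributes fractional mass rather than being dropped.

Spectra are unfolded by default (ancestral state = REF / AA tag); folding
onto the total minor allele is available and idempotent.  Serialisation is
gzip-compressed text (``.sfs.gz``) with a self-describing header.
"""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from Bio import SeqIO
from scipy.stats import hypergeom

__all__ = [
    "GenotypeTable",
    "JointSFS",
    "read_pop_map",
    "read_vcf",
    "write_vcf",
    "select_one_snp_per_locus",
    "project_site",
    "build_joint_sfs",
    "write_sfs",
    "read_sfs",
    "read_fasta_alignment",
]

logger = logging.getLogger("refugia")

POPULATIONS = ("A", "B", "C")
MISSING = -1


# ---------------------------------------------------------------------------
# Genotype table
# ---------------------------------------------------------------------------

@dataclass
class GenotypeTable:
    """Diploid genotypes at biallelic SNPs with locus and population labels.

    ``genotypes`` has shape ``(n_sites, n_samples, 2)`` with allele codes
    0 (REF/ancestral), 1 (ALT/derived) and -1 (missing).
    """

    genotypes: np.ndarray
    site_locus: np.ndarray
    site_pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    ancestral_known: np.ndarray
    samples: list[str]
    sample_pop: np.ndarray

    def __post_init__(self) -> None:
        if self.genotypes.ndim != 3 or self.genotypes.shape[2] != 2:
            raise ValueError("genotypes must have shape (sites, samples, 2)")
        bad = set(np.unique(self.sample_pop)) - set(POPULATIONS)
        if bad:
            raise ValueError(f"unknown population labels {sorted(bad)}")
        if self.n_sites and any(len(str(l)) == 0 for l in self.site_locus):
            raise ValueError("empty locus identifier")

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[1]

    def pop_indices(self, pop: str) -> np.ndarray:
        return np.flatnonzero(self.sample_pop == pop)

    def haplotypes(self, pop: str | None = None) -> np.ndarray:
        """(n_sites, copies) allele matrix, -1 for missing."""
        g = self.genotypes
        if pop is not None:
            g = g[:, self.pop_indices(pop), :]
        return g.reshape(self.n_sites, -1)

    def derived_counts(self, pop: str) -> tuple[np.ndarray, np.ndarray]:
        """Per-site (derived copies, called copies) in one population."""
        h = self.haplotypes(pop)
        called = (h >= 0).sum(axis=1)
        der = (h == 1).sum(axis=1)
        return der, called

    def take_sites(self, idx: np.ndarray) -> "GenotypeTable":
        return GenotypeTable(
            genotypes=self.genotypes[idx],
            site_locus=self.site_locus[idx],
            site_pos=self.site_pos[idx],
            ref=self.ref[idx],
            alt=self.alt[idx],
            ancestral_known=self.ancestral_known[idx],
            samples=list(self.samples),
            sample_pop=self.sample_pop.copy(),
        )

    @property
    def missing_fraction(self) -> float:
        return float((self.genotypes == MISSING).any(axis=2).mean())


def read_pop_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV (sample, population) -> mapping."""
    out: dict[str, str] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"{path}:{ln}: expected two columns")
        sample, pop = parts
        if pop not in POPULATIONS:
            raise ValueError(f"{path}:{ln}: unknown population {pop!r}")
        out[sample] = pop
    return out


# ---------------------------------------------------------------------------
# VCF I/O
# ---------------------------------------------------------------------------

def read_vcf(path: str | Path, pop_map: dict[str, str] | str | Path,
             ) -> GenotypeTable:
    """Read biallelic SNPs from a VCF v4.x file.

    Multiallelic records and indels are skipped (counts logged).  The locus
    identifier is taken from CHROM; the ancestral allele from the AA INFO
    tag when present, otherwise REF is assumed ancestral with a warning.
    """
    from cyvcf2 import VCF

    if not isinstance(pop_map, dict):
        pop_map = read_pop_map(pop_map)

    vcf = VCF(str(path), gts012=False)
    samples = list(vcf.samples)
    missing_samples = [s for s in samples if s not in pop_map]
    if missing_samples:
        raise ValueError(
            f"samples absent from population map: {missing_samples}")
    pops = np.array([pop_map[s] for s in samples])

    genos, loci, poss, refs, alts, aa_known = [], [], [], [], [], []
    n_skip_multi = n_skip_indel = 0
    n_aa_fallback = 0
    for rec_i, rec in enumerate(vcf):
        try:
            if len(rec.ALT) != 1:
                n_skip_multi += 1
                continue
            if not rec.is_snp:
                n_skip_indel += 1
                continue
            g = np.asarray(rec.genotype.array())[:, :2].astype(np.int8)
            aa = rec.INFO.get("AA")
            if aa is None:
                aa = rec.REF
                n_aa_fallback += 1
            aa = str(aa).upper()
            if aa == str(rec.ALT[0]).upper():
                # polarise: ALT is ancestral -> swap allele codes
                g = np.where(g >= 0, 1 - g, g)
                refs.append(str(rec.ALT[0]))
                alts.append(str(rec.REF))
                aa_known.append(True)
            else:
                refs.append(str(rec.REF))
                alts.append(str(rec.ALT[0]))
                aa_known.append(aa == str(rec.REF).upper())
            genos.append(g)
            loci.append(str(rec.CHROM))
            poss.append(int(rec.POS))
        except Exception as exc:  # pragma: no cover - malformed records
            raise ValueError(
                f"malformed VCF record #{rec_i + 1} in {path}: {exc}") from exc
    if n_skip_multi or n_skip_indel:
        logger.info("read_vcf(%s): skipped %d multiallelic, %d non-SNP records",
                    path, n_skip_multi, n_skip_indel)
    if not genos:
        warnings.warn(f"no biallelic SNPs found in {path}")
        geno = np.empty((0, len(samples), 2), np.int8)
    else:
        geno = np.stack(genos)
    return GenotypeTable(
        genotypes=geno,
        site_locus=np.array(loci, dtype=object),
        site_pos=np.array(poss, dtype=np.int64) if poss else np.empty(0, np.int64),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        ancestral_known=np.array(aa_known, dtype=bool),
        samples=samples,
        sample_pop=pops,
    )


def write_vcf(table: GenotypeTable, path: str | Path) -> None:
    """Write a GenotypeTable as plain-text VCF v4.2 (AA tag = ancestral)."""
    lines = [
        "##fileformat=VCFv4.2",
        "##source=refugia",
        '##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    for locus in dict.fromkeys(table.site_locus):
        lines.append(f"##contig=<ID={locus}>")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(table.samples))
    for s in range(table.n_sites):
        gts = []
        for j in range(table.n_samples):
            a, b = table.genotypes[s, j]
            gts.append("./." if a < 0 or b < 0 else f"{a}/{b}")
        aa = table.ref[s] if table.ancestral_known[s] else "."
        lines.append("\t".join([
            str(table.site_locus[s]), str(table.site_pos[s]), ".",
            str(table.ref[s]), str(table.alt[s]), ".", "PASS",
            f"AA={aa}", "GT", *gts,
        ]))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def select_one_snp_per_locus(table: GenotypeTable, rng) -> GenotypeTable:
    """Retain one uniformly chosen SNP per locus (deterministic under seed,
    stable site order, idempotent on already-filtered tables)."""
    rng = np.random.default_rng(rng)
    chosen = []
    seen: dict[str, list[int]] = {}
    for i, locus in enumerate(table.site_locus):
        seen.setdefault(str(locus), []).append(i)
    for locus in dict.fromkeys(str(l) for l in table.site_locus):
        idx = seen[locus]
        chosen.append(idx[rng.integers(len(idx))] if len(idx) > 1 else idx[0])
    chosen = np.sort(np.array(chosen, dtype=np.int64))
    return table.take_sites(chosen)


# ---------------------------------------------------------------------------
# Hypergeometric projection
# ---------------------------------------------------------------------------

def project_site(derived: int, present: int, target: int) -> np.ndarray:
    """Distribution of the derived count after downsampling ``present``
    called copies (of which ``derived`` carry the derived allele) to
    ``target`` copies without replacement.

    ``P(j) = C(i, j) C(n-i, m-j) / C(n, m)``.
    """
    if not (0 <= derived <= present):
        raise ValueError("need 0 <= derived <= present")
    if not (1 <= target <= present):
        raise ValueError("projection size must be in [1, present]")
    j = np.arange(target + 1)
    return hypergeom.pmf(j, present, derived, target)


# ---------------------------------------------------------------------------
# Joint SFS
# ---------------------------------------------------------------------------

@dataclass
class JointSFS:
    """Joint SFS counts at fixed projected sizes ``(m_A, m_B, m_C)``.

    ``counts[iA, iB, iC]`` may be fractional (expected projection).  Sites
    that become monomorphic after projection, or lack coverage for the
    projection, are tallied in ``dropped`` so that retained + dropped mass
    always equals the input site count.
    """

    sizes: tuple[int, int, int]
    counts: np.ndarray
    folded: bool = False
    n_input_sites: float = 0.0
    dropped: dict = field(default_factory=lambda: {
        "monomorphic": 0.0, "low_coverage": 0.0})

    def __post_init__(self) -> None:
        expect = tuple(m + 1 for m in self.sizes)
        if self.counts.shape != expect:
            raise ValueError(
                f"counts shape {self.counts.shape} != sizes+1 {expect}")
        if np.any(self.counts < -1e-12):
            raise ValueError("negative SFS counts")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def cells(self) -> tuple[np.ndarray, np.ndarray]:
        """(configs, counts) for non-empty cells."""
        idx = np.argwhere(self.counts > 0)
        return idx, self.counts[tuple(idx.T)]

    def fold(self) -> "JointSFS":
        """Fold onto the total minor allele: a configuration whose summed
        derived count exceeds half the total sample is mapped onto its
        complement.  Idempotent."""
        if self.folded:
            return replace(self, counts=self.counts.copy())
        mA, mB, mC = self.sizes
        T = mA + mB + mC
        iA, iB, iC = np.meshgrid(np.arange(mA + 1), np.arange(mB + 1),
                                 np.arange(mC + 1), indexing="ij")
        tot = iA + iB + iC
        out = np.zeros_like(self.counts)
        flip = tot * 2 > T
        # ties (tot == T/2): keep the lexicographically smaller configuration
        if T % 2 == 0:
            tie = tot * 2 == T
            comp_lex = ((mA - iA) * (mB + 1) + (mB - iB)) * (mC + 1) + (mC - iC)
            own_lex = (iA * (mB + 1) + iB) * (mC + 1) + iC
            flip = flip | (tie & (comp_lex < own_lex))
        src = self.counts
        np.add.at(out, (np.where(flip, mA - iA, iA),
                        np.where(flip, mB - iB, iB),
                        np.where(flip, mC - iC, iC)), src)
        return replace(self, counts=out, folded=True)


def build_joint_sfs(table: GenotypeTable,
                    projection_sizes: tuple[int, int, int] | None = None,
                    folded: bool = False,
                    projection_fraction: float = 0.8) -> JointSFS:
    """Build the joint SFS from a genotype table by expected projection.

    ``projection_sizes`` are haploid; when omitted they default to
    ``floor(projection_fraction * max called copies)`` per population
    (at least 1).  Sites with fewer called copies than the projection size
    in any population are counted as dropped (low coverage); projection
    mass landing on the monomorphic corners is counted as dropped
    (monomorphic).  If the ancestral state is unknown at any site the
    spectrum is folded with a warning.
    """
    der = {}
    called = {}
    for p in POPULATIONS:
        der[p], called[p] = table.derived_counts(p)

    if projection_sizes is None:
        projection_sizes = tuple(
            max(1, int(np.floor(projection_fraction * called[p].max())))
            if table.n_sites else 1
            for p in POPULATIONS)
    mA, mB, mC = projection_sizes
    for p, m in zip(POPULATIONS, projection_sizes):
        if table.n_sites and m > called[p].max():
            raise ValueError(
                f"projection size {m} for {p} exceeds the maximum called "
                f"copies ({called[p].max()})")

    counts = np.zeros((mA + 1, mB + 1, mC + 1))
    dropped = {"monomorphic": 0.0, "low_coverage": 0.0}

    if not np.all(table.ancestral_known) and not folded:
        warnings.warn("ancestral state unknown at some sites; folding the "
                      "spectrum")
        folded = True

    if table.n_sites:
        ok = np.ones(table.n_sites, dtype=bool)
        for p, m in zip(POPULATIONS, projection_sizes):
            ok &= called[p] >= m
        dropped["low_coverage"] = float((~ok).sum())
        if ok.any():
            vs = []
            for p, m in zip(POPULATIONS, projection_sizes):
                j = np.arange(m + 1)
                vs.append(hypergeom.pmf(j[None, :], called[p][ok, None],
                                        der[p][ok, None], m))
            vA, vB, vC = vs
            counts = np.einsum("si,sj,sk->ijk", vA, vB, vC)
            dropped["monomorphic"] = float(counts[0, 0, 0]
                                           + counts[mA, mB, mC])
            counts[0, 0, 0] = 0.0
            counts[mA, mB, mC] = 0.0

    sfs = JointSFS(sizes=(mA, mB, mC), counts=counts, folded=False,
                   n_input_sites=float(table.n_sites), dropped=dropped)
    return sfs.fold() if folded else sfs


# ---------------------------------------------------------------------------
# SFS serialisation
# ---------------------------------------------------------------------------

_SFS_MAGIC = "#refugia-sfs v1"


def write_sfs(sfs: JointSFS, path: str | Path) -> None:
    lines = [
        _SFS_MAGIC,
        "#sizes: {} {} {}".format(*sfs.sizes),
        f"#folded: {int(sfs.folded)}",
        f"#n_input_sites: {sfs.n_input_sites!r}",
        f"#dropped_monomorphic: {sfs.dropped['monomorphic']!r}",
        f"#dropped_low_coverage: {sfs.dropped['low_coverage']!r}",
        "iA\tiB\tiC\tcount",
    ]
    idx, vals = sfs.cells()
    for (a, b, c), v in zip(idx, vals):
        lines.append(f"{a}\t{b}\t{c}\t{float(v)!r}")
    with gzip.open(path, "wt") as fh:
        fh.write("\n".join(lines) + "\n")


def read_sfs(path: str | Path) -> JointSFS:
    import zlib

    try:
        with gzip.open(path, "rt") as fh:
            lines = fh.read().splitlines()
    except (OSError, EOFError, gzip.BadGzipFile, zlib.error) as exc:
        raise ValueError(f"cannot read {path}: {exc}") from exc
    if not lines or lines[0] != _SFS_MAGIC:
        raise ValueError(f"{path}: not a refugia SFS file")
    header = {}
    body_start = 0
    for i, line in enumerate(lines[1:], 1):
        if line.startswith("#"):
            key, _, val = line[1:].partition(":")
            header[key.strip()] = val.strip()
        else:
            body_start = i
            break
    try:
        sizes = tuple(int(x) for x in header["sizes"].split())
        folded = bool(int(header["folded"]))
        n_input = float(header["n_input_sites"])
        dropped = {"monomorphic": float(header["dropped_monomorphic"]),
                   "low_coverage": float(header["dropped_low_coverage"])}
    except (KeyError, ValueError) as exc:
        raise ValueError(f"{path}: malformed SFS header: {exc}") from exc
    counts = np.zeros(tuple(m + 1 for m in sizes))
    for line in lines[body_start + 1:]:
        if not line.strip():
            continue
        a, b, c, v = line.split("\t")
        a, b, c = int(a), int(b), int(c)
        if not all(0 <= i <= m for i, m in zip((a, b, c), sizes)):
            raise ValueError(f"{path}: cell ({a},{b},{c}) outside shape")
        counts[a, b, c] = float(v)
    return JointSFS(sizes=sizes, counts=counts, folded=folded,
                    n_input_sites=n_input, dropped=dropped)


# ---------------------------------------------------------------------------
# FASTA alignments
# ---------------------------------------------------------------------------

_UNAMBIGUOUS = set("ACGTacgt")


def read_fasta_alignment(path: str | Path):
    """Read an aligned FASTA into (names, character matrix).

    Sequences must be equal length; IUPAC ambiguity codes, gaps and N are
    treated as missing for downstream statistics (mapped to ``N``).
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no sequences found")
    lengths = {len(r.seq) for r in records}
    if len(lengths) != 1:
        raise ValueError(f"{path}: ragged alignment (lengths {sorted(lengths)})")
    names = [r.id for r in records]
    mat = np.array([
        [ch.upper() if ch in _UNAMBIGUOUS else "N" for ch in str(r.seq)]
        for r in records
    ], dtype="U1")
    return names, mat
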