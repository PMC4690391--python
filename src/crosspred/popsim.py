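"""Multi-population genotype simulation and PLINK-format I/O.

The simulator stands in for real multi-breed cattle genotypes.  It needs
to reproduce three structural properties that drive across-population
prediction: linkage disequilibrium that decays with genetic distance,
allele-frequency (and LD-pattern) divergence between populations, and
paternal half-sib family structure in the large population.  It does so
with a founder-haplotype mosaic (LD) followed by Wright-Fisher forward
simulation with recombination (divergence by pure drift) and a final
sire-limited generation (families).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from crosspred._kernels import wf_generations, drop_offspring

UNKNOWN_PARENT = "0"

#: base pairs per Morgan used to lay SNPs on a physical map (1 cM/Mb).
BP_PER_MORGAN = 100_000_000


@dataclass(frozen=True)
class PopSimConfig:
    """Parameters of the three-population simulation.

    Defaults emulate a panel of 1033 + 105 + 147 cows genotyped on three
    chromosomes with ~31.5k SNPs retained after a 0.5 % MAF filter.
    """

    n_individuals: tuple[int, ...] = (1033, 105, 147)
    population_labels: tuple[str, ...] = ("HF", "GWH", "MRY")
    n_chromosomes: int = 3
    chromosome_labels: tuple[str, ...] = ("13", "23", "28")
    # pre-filter count per chromosome; ~78 % survive the default MAF
    # filter, so three chromosomes retain ~31.5k SNPs
    n_snps_per_chromosome: int = 13_450
    chromosome_length_morgans: float = 1.0
    n_founder_haplotypes: int = 10
    divergence_generations: int = 50
    within_pop_ne: tuple[int, ...] = (500, 250, 250)
    half_sib_family_size: int = 20
    maf_threshold: float = 0.005
    mosaic_switch_rate: float = 30.0  # founder switches per Morgan
    freq_truncation: float = 0.05    # founder frequencies kept in [t, 1-t]
    seed: int = 0

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        counts = (self.n_chromosomes, self.n_snps_per_chromosome,
                  self.n_founder_haplotypes, self.half_sib_family_size,
                  *self.n_individuals, *self.within_pop_ne)
        if any(c <= 0 for c in counts):
            raise ValueError("all counts must be strictly positive")
        if self.divergence_generations < 0:
            raise ValueError("divergence_generations must be >= 0")
        if not 0.0 <= self.maf_threshold < 0.5:
            raise ValueError("maf_threshold must lie in [0, 0.5)")
        if len(set(self.population_labels)) != len(self.population_labels):
            raise ValueError("population labels must be unique")
        if len(self.n_individuals) != len(self.population_labels):
            raise ValueError("one size per population label required")
        if len(self.within_pop_ne) != len(self.population_labels):
            raise ValueError("one Ne per population required")
        if len(self.chromosome_labels) != self.n_chromosomes:
            raise ValueError("one label per chromosome required")
        if self.n_founder_haplotypes < 2:
            raise ValueError("n_founder_haplotypes must be >= 2")
        if self.chromosome_length_morgans <= 0:
            raise ValueError("chromosome length must be positive")

    @classmethod
    def from_file(cls, path) -> "PopSimConfig":
        """Read a plain key = value text file; tuples are comma-separated."""
        kwargs = {}
        tuple_int = {"n_individuals", "within_pop_ne"}
        tuple_str = {"population_labels", "chromosome_labels"}
        floats = {"chromosome_length_morgans", "maf_threshold",
                  "mosaic_switch_rate", "freq_truncation"}
        with open(path) as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                key, _, val = line.partition("=")
                key = key.strip()
                val = val.strip()
                if key in tuple_int:
                    kwargs[key] = tuple(int(v) for v in val.split(","))
                elif key in tuple_str:
                    kwargs[key] = tuple(v.strip() for v in val.split(","))
                elif key in floats:
                    kwargs[key] = float(val)
                else:
                    kwargs[key] = int(val)
        return cls(**kwargs)


def _seed_streams(seed: int, n: int) -> list[int]:
    """Expand one master seed into independent 31-bit child seeds."""
    ss = np.random.SeedSequence(seed)
    return [int(s) & 0x7FFFFFFF for s in ss.generate_state(n, dtype=np.uint32)]


@dataclass
class GenotypePanel:
    """Individuals x SNPs allele-count matrix with map and labels."""

    allele_counts: np.ndarray            # (n, m) int8, entries in {0,1,2}
    individual_ids: np.ndarray           # (n,) str
    population_labels: np.ndarray        # (n,) str
    snp_map: pd.DataFrame                # snp_id, chromosome, position, genetic_position

    def __post_init__(self):
        self.allele_counts = np.asarray(self.allele_counts, dtype=np.int8)
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        self.population_labels = np.asarray(self.population_labels, dtype=object)
        n, m = self.allele_counts.shape
        if len(self.individual_ids) != n or len(self.population_labels) != n:
            raise ValueError("id/label length does not match genotype rows")
        if len(self.snp_map) != m:
            raise ValueError("snp_map length does not match genotype columns")

    @property
    def n_individuals(self) -> int:
        return self.allele_counts.shape[0]

    @property
    def n_snps(self) -> int:
        return self.allele_counts.shape[1]

    @property
    def populations(self) -> tuple[str, ...]:
        seen = []
        for p in self.population_labels:
            if p not in seen:
                seen.append(p)
        return tuple(seen)

    def allele_frequencies(self) -> np.ndarray:
        """Combined-data frequency of the counted allele, per SNP."""
        return self.allele_counts.mean(axis=0) / 2.0

    def individuals_of(self, *populations: str) -> np.ndarray:
        """Row indices of the individuals in the given population(s)."""
        mask = np.isin(np.asarray(self.population_labels, dtype=str),
                       np.asarray(populations, dtype=str))
        return np.flatnonzero(mask)

    def subset_snps(self, mask_or_ids) -> "GenotypePanel":
        arr = np.asarray(mask_or_ids)
        if arr.dtype == bool:
            idx = np.flatnonzero(arr)
        elif np.issubdtype(arr.dtype, np.integer):
            idx = arr
        else:
            pos = {s: i for i, s in enumerate(self.snp_map["snp_id"])}
            missing = [s for s in arr if s not in pos]
            if missing:
                raise KeyError(f"unknown snp ids: {missing[:5]}")
            idx = np.array([pos[s] for s in arr], dtype=int)
        return GenotypePanel(
            allele_counts=self.allele_counts[:, idx],
            individual_ids=self.individual_ids.copy(),
            population_labels=self.population_labels.copy(),
            snp_map=self.snp_map.iloc[idx].reset_index(drop=True),
        )

    def snp_indices(self, snp_ids) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.snp_map["snp_id"])}
        return np.array([pos[s] for s in snp_ids], dtype=int)


def _make_snp_map(config: PopSimConfig) -> pd.DataFrame:
    rows = []
    m = config.n_snps_per_chromosome
    length = config.chromosome_length_morgans
    for chrom in config.chromosome_labels:
        bp = np.round(np.linspace(1, length * BP_PER_MORGAN, m)).astype(np.int64)
        bp = np.maximum.accumulate(bp)  # keep strictly increasing
        bp += np.arange(m)
        gpos = np.linspace(0.0, length, m)
        for k in range(m):
            rows.append((f"chr{chrom}_snp{k:06d}", chrom, int(bp[k]), gpos[k]))
    return pd.DataFrame(rows, columns=["snp_id", "chromosome", "position",
                                       "genetic_position"])


def _chromosome_blocks(snp_map: pd.DataFrame):
    """(start, end, length, gpos) arrays for the kernels."""
    chroms = snp_map["chromosome"].to_numpy()
    gpos = snp_map["genetic_position"].to_numpy(dtype=float)
    starts, ends, lengths = [], [], []
    i = 0
    m = len(snp_map)
    while i < m:
        j = i
        while j < m and chroms[j] == chroms[i]:
            j += 1
        starts.append(i)
        ends.append(j)
        lengths.append(max(gpos[j - 1] - gpos[i], 1e-9))
        i = j
    return (np.array(starts, dtype=np.int64), np.array(ends, dtype=np.int64),
            np.array(lengths, dtype=float), gpos)


def simulate_base_haplotypes(config: PopSimConfig, n_haplotypes: int | None = None):
    """Draw a pool of base haplotypes as first-order founder mosaics.

    Per chromosome, ``n_founder_haplotypes`` founder sequences are drawn
    with per-SNP allele frequencies from a symmetric U-shaped Beta(0.5,
    0.5) truncated away from fixation.  Each pool haplotype copies one
    founder at a time, switching to a random founder between adjacent
    SNPs with probability ``mosaic_switch_rate x genetic distance`` —
    LD therefore decays on a 1/switch_rate Morgan scale.

    Returns (pool, snp_map): pool is (n_haplotypes, n_snps) int8 in {0,1}.
    """
    config.validate()
    if n_haplotypes is None:
        n_haplotypes = 2 * sum(config.within_pop_ne)
    snp_map = _make_snp_map(config)
    rng = np.random.default_rng(_seed_streams(config.seed, 4)[0])
    starts, ends, _, gpos = _chromosome_blocks(snp_map)
    m_total = len(snp_map)
    nf = config.n_founder_haplotypes
    pool = np.empty((n_haplotypes, m_total), dtype=np.int8)
    for lo, hi in zip(starts, ends):
        m = hi - lo
        # truncated U-shaped founder allele frequencies
        p = rng.beta(0.5, 0.5, size=m)
        t = config.freq_truncation
        p = t + p * (1 - 2 * t)
        founders = (rng.random((nf, m)) < p).astype(np.int8)
        gaps = np.diff(gpos[lo:hi])
        p_switch = np.clip(config.mosaic_switch_rate * gaps, 0.0, 1.0)
        # mosaic: segment ids from cumulative switch indicators, then a
        # random founder per segment
        switches = rng.random((n_haplotypes, m - 1)) < p_switch[None, :]
        seg = np.zeros((n_haplotypes, m), dtype=np.int64)
        seg[:, 1:] = np.cumsum(switches, axis=1)
        n_seg = seg[:, -1].max() + 1
        choice = rng.integers(0, nf, size=(n_haplotypes, n_seg))
        fid = np.take_along_axis(choice, seg, axis=1)
        pool[:, lo:hi] = founders[fid, np.arange(m)[None, :]]
    return pool, snp_map


@dataclass
class SimulatedData:
    panel: GenotypePanel
    pedigree: pd.DataFrame


def evolve_populations(pool: np.ndarray, snp_map: pd.DataFrame,
                       config: PopSimConfig) -> SimulatedData:
    """Found populations from disjoint base-haplotype draws and drift them.

    Each population is founded with 2*Ne haplotypes, evolves
    ``divergence_generations`` of Wright-Fisher random mating with
    recombination, and then produces its genotyped final generation.
    The largest population's final generation is sired by a limited set
    of sires (``half_sib_family_size`` daughters each), creating
    paternal half-sib families.  The pedigree records the final two
    generations; the parent generation are unknown-parent base animals.
    """
    config.validate()
    if any(n < 2 for n in config.n_individuals):
        raise ValueError("population size must be at least 2")
    need = 2 * sum(config.within_pop_ne)
    if pool.shape[0] < need:
        raise ValueError(f"pool has {pool.shape[0]} haplotypes, "
                         f"need {need} for disjoint founding draws")
    seeds = _seed_streams(config.seed, 4)
    rng = np.random.default_rng(seeds[1])
    starts, ends, lengths, gpos = _chromosome_blocks(snp_map)
    perm = rng.permutation(pool.shape[0])

    largest = int(np.argmax(config.n_individuals))
    geno_rows, ids, labels = [], [], []
    ped_rows = []
    offset = 0
    for ip, (pop, n_final, ne) in enumerate(zip(config.population_labels,
                                                config.n_individuals,
                                                config.within_pop_ne)):
        take = perm[offset:offset + 2 * ne]
        offset += 2 * ne
        haps = np.ascontiguousarray(pool[take])
        wf_seed = int(rng.integers(2 ** 31))
        if config.divergence_generations > 0:
            haps = wf_generations(haps, config.divergence_generations, ne,
                                  starts, ends, lengths, gpos, wf_seed)
        # parent generation = final WF generation (base animals)
        parent_ids = [f"{pop}_G0_{i:05d}" for i in range(ne)]
        for pid in parent_ids:
            ped_rows.append((pid, UNKNOWN_PARENT, UNKNOWN_PARENT, pop, 0))
        if ip == largest:
            n_sires = int(np.ceil(n_final / config.half_sib_family_size))
            n_sires = min(n_sires, ne - 1)
            sire_pool = rng.choice(ne, size=n_sires, replace=False)
            sires = np.repeat(sire_pool, config.half_sib_family_size)[:n_final]
        else:
            sires = rng.integers(0, ne, size=n_final)
        dams = rng.integers(0, ne, size=n_final)
        clash = dams == sires
        while clash.any():
            dams[clash] = rng.integers(0, ne, size=int(clash.sum()))
            clash = dams == sires
        off_seed = int(rng.integers(2 ** 31))
        off = drop_offspring(haps, sires.astype(np.int64),
                             dams.astype(np.int64), starts, ends, lengths,
                             gpos, off_seed)
        counts = (off[0::2].astype(np.int16) + off[1::2]).astype(np.int8)
        geno_rows.append(counts)
        for i in range(n_final):
            iid = f"{pop}_G1_{i:05d}"
            ids.append(iid)
            labels.append(pop)
            ped_rows.append((iid, parent_ids[sires[i]], parent_ids[dams[i]],
                             pop, 1))

    panel = GenotypePanel(
        allele_counts=np.vstack(geno_rows),
        individual_ids=np.array(ids, dtype=object),
        population_labels=np.array(labels, dtype=object),
        snp_map=snp_map.copy(),
    )
    pedigree = pd.DataFrame(ped_rows, columns=["individual_id", "sire_id",
                                               "dam_id", "population",
                                               "generation"])
    return SimulatedData(panel=panel, pedigree=pedigree)


def apply_maf_filter(panel: GenotypePanel, threshold: float | None = None) -> GenotypePanel:
    """Keep SNPs whose combined-data MAF is strictly above the threshold.

    SNPs with minor allele frequency equal to or lower than the
    threshold are deleted, computed on the pooled data of all
    populations.  Idempotent.
    """
    if threshold is None:
        threshold = 0.005
    if not 0.0 <= threshold < 0.5:
        raise ValueError("threshold must lie in [0, 0.5)")
    if panel.n_snps == 0 or panel.n_individuals == 0:
        raise ValueError("panel is empty")
    p = panel.allele_frequencies()
    maf = np.minimum(p, 1.0 - p)
    return panel.subset_snps(maf > threshold)


def simulate_panel(config: PopSimConfig) -> SimulatedData:
    """End-to-end: base haplotypes -> drift/families -> MAF filter."""
    pool, snp_map = simulate_base_haplotypes(config)
    data = evolve_populations(pool, snp_map, config)
    data.panel = apply_maf_filter(data.panel, config.maf_threshold)
    return data


# ---------------------------------------------------------------------------
# PLINK bed/bim/fam I/O (SNP-major), pedigree as a TSV side file.
# ---------------------------------------------------------------------------

_BED_MAGIC = b"\x6c\x1b\x01"
# 2-bit PLINK codes -> count of the A1 allele; 1 (0b01) is "missing"
_DECODE = np.array([2, -1, 1, 0], dtype=np.int8)


def _pack_bed_column(counts: np.ndarray) -> np.ndarray:
    """Pack one SNP's allele counts into PLINK 2-bit codes."""
    code = np.empty(len(counts), dtype=np.uint8)
    code[counts == 2] = 0b00
    code[counts == 1] = 0b10
    code[counts == 0] = 0b11
    n_bytes = (len(counts) + 3) // 4
    padded = np.zeros(n_bytes * 4, dtype=np.uint8)
    padded[:len(counts)] = code
    padded = padded.reshape(n_bytes, 4)
    return (padded[:, 0] | (padded[:, 1] << 2) | (padded[:, 2] << 4)
            | (padded[:, 3] << 6)).astype(np.uint8)


def write_genotypes(panel: GenotypePanel, prefix, pedigree: pd.DataFrame | None = None) -> None:
    """Write panel as PLINK bed/bim/fam (+ ``<prefix>.pedigree.tsv``).

    The population label is stored in the family-ID column of the .fam
    file.  A1 is the counted allele ('A'), A2 the other ('B'); the .bim
    genetic position is in Morgan.
    """
    prefix = str(prefix)
    n, m = panel.allele_counts.shape
    with open(prefix + ".bed", "wb") as fh:
        fh.write(_BED_MAGIC)
        for j in range(m):
            fh.write(_pack_bed_column(panel.allele_counts[:, j]).tobytes())
    bim = pd.DataFrame({
        "chromosome": panel.snp_map["chromosome"],
        "snp_id": panel.snp_map["snp_id"],
        "genetic_position": panel.snp_map["genetic_position"],
        "position": panel.snp_map["position"],
        "a1": "A",
        "a2": "B",
    })
    bim.to_csv(prefix + ".bim", sep="\t", header=False, index=False)
    fam = pd.DataFrame({
        "fid": panel.population_labels,
        "iid": panel.individual_ids,
        "pat": UNKNOWN_PARENT,
        "mat": UNKNOWN_PARENT,
        "sex": 0,
        "phe": -9,
    })
    fam.to_csv(prefix + ".fam", sep="\t", header=False, index=False)
    if pedigree is not None:
        pedigree.to_csv(prefix + ".pedigree.tsv", sep="\t", index=False)


def read_genotypes(prefix):
    """Read PLINK bed/bim/fam written by :func:`write_genotypes`.

    Returns (panel, pedigree-or-None).  Raises ``ValueError`` naming the
    byte offset on a bad magic number or a truncated .bed payload.
    """
    import os
    prefix = str(prefix)
    fam = pd.read_csv(prefix + ".fam", sep=r"\s+", header=None,
                      names=["fid", "iid", "pat", "mat", "sex", "phe"],
                      dtype={"fid": str, "iid": str})
    bim = pd.read_csv(prefix + ".bim", sep=r"\s+", header=None,
                      names=["chromosome", "snp_id", "genetic_position",
                             "position", "a1", "a2"],
                      dtype={"chromosome": str, "snp_id": str})
    n, m = len(fam), len(bim)
    n_bytes = (n + 3) // 4
    with open(prefix + ".bed", "rb") as fh:
        raw = fh.read()
    if len(raw) < 3 or raw[:3] != _BED_MAGIC:
        bad = next((i for i in range(min(3, len(raw)))
                    if i >= len(raw) or raw[i] != _BED_MAGIC[i]), len(raw))
        raise ValueError(f"not a PLINK bed file: bad magic at byte offset {bad}")
    expected = 3 + n_bytes * m
    if len(raw) != expected:
        raise ValueError(
            f"truncated or oversized bed payload: expected {expected} bytes, "
            f"got {len(raw)} (first inconsistency at byte offset {min(len(raw), expected)})")
    body = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(m, n_bytes)
    # unpack 2-bit codes, individuals in the low bits first
    codes = np.empty((m, n_bytes * 4), dtype=np.uint8)
    codes[:, 0::4] = body & 0b11
    codes[:, 1::4] = (body >> 2) & 0b11
    codes[:, 2::4] = (body >> 4) & 0b11
    codes[:, 3::4] = (body >> 6) & 0b11
    counts = _DECODE[codes[:, :n]].T  # (n, m)
    if (counts < 0).any():
        raise ValueError("bed file contains missing genotypes; "
                         "the simulator never writes them")
    snp_map = bim[["snp_id", "chromosome", "position", "genetic_position"]].copy()
    panel = GenotypePanel(
        allele_counts=counts.astype(np.int8),
        individual_ids=fam["iid"].to_numpy(dtype=object),
        population_labels=fam["fid"].to_numpy(dtype=object),
        snp_map=snp_map.reset_index(drop=True),
    )
    ped_path = prefix + ".pedigree.tsv"
    pedigree = None
    if os.path.exists(ped_path):
        pedigree = pd.read_csv(ped_path, sep="\t",
                               dtype={"individual_id": str, "sire_id": str,
                                      "dam_id": str, "population": str})
    return panel, pedigree
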