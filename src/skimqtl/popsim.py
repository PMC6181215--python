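"""Synthetic RIL population generator.

Simulates a biparental single-seed-descent (SSD) pedigree explicitly,
generation by generation, so that every line carries a known mosaic of
parental blocks and the true recombination breakpoints are available for
oracle tests.  A skim-coverage observation layer then thins and perturbs the
true calls, and a phenotype layer plants additive QTL (optionally pleiotropic)
on top of line, line-by-environment and residual variance components.

Crossovers per meiosis are Poisson with rate equal to the chromosome's
genetic length in Morgans; crossover positions are uniform on the genetic
scale and the cM<->bp relationship is linear within a chromosome (no
interference).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codes import A, B, HET, MISSING


# ---------------------------------------------------------------------------
# specs

@dataclass(frozen=True)
class ChromSpec:
    name: str
    length_bp: int
    length_cm: float

    @property
    def morgans(self) -> float:
        return self.length_cm / 100.0


@dataclass
class GeneticMapSpec:
    """Chromosome sizes plus SNP coordinates.

    ``snp_positions[chrom]`` must be a strictly increasing integer array of
    1-based bp coordinates; each chromosome needs at least two SNPs.
    """

    chromosomes: list[ChromSpec]
    snp_positions: dict[str, np.ndarray]
    mapping_function: str = "kosambi"

    def __post_init__(self):
        if self.mapping_function not in ("kosambi", "haldane"):
            raise ValueError(f"unknown mapping function {self.mapping_function!r}")
        if not self.chromosomes:
            raise ValueError("need at least one chromosome")
        for c in self.chromosomes:
            if c.length_bp <= 0 or c.length_cm < 0:
                raise ValueError(f"bad lengths for chromosome {c.name}")
            pos = np.asarray(self.snp_positions[c.name])
            if pos.size < 2:
                raise ValueError(f"chromosome {c.name} needs >=2 SNPs")
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"SNP positions not strictly increasing on {c.name}")
            if pos[0] < 1 or pos[-1] > c.length_bp:
                raise ValueError(f"SNP positions out of range on {c.name}")
            self.snp_positions[c.name] = pos.astype(np.int64)

    @property
    def chrom_names(self) -> list[str]:
        return [c.name for c in self.chromosomes]

    def chrom(self, name: str) -> ChromSpec:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(name)

    @property
    def n_snps(self) -> int:
        return int(sum(len(self.snp_positions[c.name]) for c in self.chromosomes))


@dataclass(frozen=True)
class PedigreeParams:
    """SSD pedigree: ``generation`` = g means an F_g individual, i.e. g-1
    rounds of selfing applied to the F1."""

    n_lines: int
    generation: int = 8

    def __post_init__(self):
        if self.n_lines < 2:
            raise ValueError("n_lines must be >= 2")
        if self.generation < 2:
            raise ValueError("generation must be >= 2")


@dataclass(frozen=True)
class SkimObservationModel:
    observation_rate: float
    error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for r in (self.observation_rate, self.error_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must be in [0, 1]")


@dataclass(frozen=True)
class TraitSpec:
    name: str
    mu: float = 0.0
    qtl: tuple = ()                     # ((chrom, bp, additive_effect), ...)
    var_g_residual: float = 0.0
    var_ge: float = 0.0
    var_e: float = 0.0

    def __post_init__(self):
        for v in (self.var_g_residual, self.var_ge, self.var_e):
            if v < 0:
                raise ValueError("variances must be >= 0")


@dataclass
class PhenotypeModel:
    """Balanced multi-environment trial design with planted additive QTL.

    Pleiotropy is expressed by listing the same (chrom, bp) locus in several
    traits with per-trait signed effects.  ``mendelian_locus`` adds a binary
    trait fully determined by the genotype at that locus (B homozygote -> 1).
    """

    traits: list[TraitSpec]
    n_environments: int = 1
    n_replicates: int = 1
    env_effects: np.ndarray | None = None
    mendelian_locus: tuple | None = None      # (trait_name, chrom, bp)

    def __post_init__(self):
        if self.n_environments < 1 or self.n_replicates < 1:
            raise ValueError("need >=1 environment and replicate")
        if self.env_effects is None:
            self.env_effects = np.zeros(self.n_environments)
        self.env_effects = np.asarray(self.env_effects, dtype=float)
        if len(self.env_effects) != self.n_environments:
            raise ValueError("env_effects length must equal n_environments")


# ---------------------------------------------------------------------------
# genome simulation

@dataclass
class RilTruth:
    """True genotypes plus the breakpoint structure the simulator used."""

    mapspec: GeneticMapSpec
    lines: list[str]
    chroms: np.ndarray          # per-SNP chromosome name
    pos: np.ndarray             # per-SNP bp
    genotypes: np.ndarray       # (n_lines, n_snps) in {A, B, HET}
    #: (line, chrom) -> list of (left_bp, right_bp) intervals bracketing each
    #: A<->B transition of the homozygous-SNP skeleton
    breakpoints: dict
    #: (line, chrom) -> list of (genotype, first_bp, last_bp) homozygous runs
    blocks: dict

    def snp_indices(self, chrom: str) -> np.ndarray:
        return np.flatnonzero(self.chroms == chrom)

    def locus_index(self, chrom: str, bp: int) -> int:
        """Index of the SNP nearest to (chrom, bp)."""
        idx = self.snp_indices(chrom)
        if idx.size == 0:
            raise KeyError(f"no SNPs on chromosome {chrom}")
        return int(idx[np.argmin(np.abs(self.pos[idx] - bp))])


def _gamete(hap1, hap2, length_bp, morgans, rng):
    """One meiotic product. Haplotypes are (ends, origins) arrays where
    origins[i] applies to [prev_end, ends[i])."""
    n_co = rng.poisson(morgans) if morgans > 0 else 0
    start = int(rng.integers(2))
    haps = (hap1, hap2)
    if n_co == 0:
        ends, orig = haps[start]
        return ends.copy(), orig.copy()
    xs = np.sort(rng.uniform(0.0, length_bp, size=n_co))
    # segment s covers [seg_bounds[s], seg_bounds[s+1]) and copies haplotype
    # (start + s) % 2
    seg_bounds = np.concatenate(([0.0], xs, [float(length_bp)]))
    ends_out, orig_out = [], []
    for s in range(n_co + 1):
        lo, hi = seg_bounds[s], seg_bounds[s + 1]
        ends, orig = haps[(start + s) % 2]
        i0 = int(np.searchsorted(ends, lo, side="right"))
        i1 = int(np.searchsorted(ends, hi, side="left"))
        for i in range(i0, min(i1 + 1, len(ends))):
            e = min(float(ends[i]), hi)
            if e > lo:
                ends_out.append(e)
                orig_out.append(orig[i])
                lo = e
            if e >= hi:
                break
    # merge adjacent equal-origin segments
    m_ends, m_orig = [], []
    for e, o in zip(ends_out, orig_out):
        if m_orig and m_orig[-1] == o:
            m_ends[-1] = e
        else:
            m_ends.append(e)
            m_orig.append(o)
    return np.asarray(m_ends), np.asarray(m_orig, dtype=np.int8)


def _origins_at(hap, positions):
    ends, orig = hap
    return orig[np.searchsorted(ends, positions, side="left")]


def simulate_ril_genomes(mapspec: GeneticMapSpec, ped: PedigreeParams, seed: int) -> RilTruth:
    """Simulate SSD RIL genomes and return true genotypes plus breakpoints.

    Each line is advanced independently from the F1 (one full parental
    chromosome per homolog) through ``generation - 1`` rounds of selfing.
    Breakpoints are reported on the homozygous-SNP skeleton: residual
    heterozygous sites (expected fraction 2^-(g-1)) are skipped and each
    A<->B transition is bracketed by the flanking homozygous SNP coordinates.
    """
    rng = np.random.default_rng(seed)
    lines = [f"RIL{i + 1:03d}" for i in range(ped.n_lines)]
    chroms_col, pos_col = [], []
    for c in mapspec.chromosomes:
        p = mapspec.snp_positions[c.name]
        chroms_col.append(np.repeat(c.name, len(p)))
        pos_col.append(p)
    chroms_arr = np.concatenate(chroms_col)
    pos_arr = np.concatenate(pos_col)

    geno = np.empty((ped.n_lines, len(pos_arr)), dtype=np.int8)
    breakpoints, blocks = {}, {}

    for li, line in enumerate(lines):
        col = 0
        for c in mapspec.chromosomes:
            positions = mapspec.snp_positions[c.name]
            L = float(c.length_bp)
            h1 = (np.array([L]), np.array([A], dtype=np.int8))
            h2 = (np.array([L]), np.array([B], dtype=np.int8))
            for _ in range(ped.generation - 1):
                g1 = _gamete(h1, h2, L, c.morgans, rng)
                g2 = _gamete(h1, h2, L, c.morgans, rng)
                h1, h2 = g1, g2
            a1 = _origins_at(h1, positions.astype(float) - 0.5)
            a2 = _origins_at(h2, positions.astype(float) - 0.5)
            g = np.where(a1 == a2, a1, HET).astype(np.int8)
            geno[li, col:col + len(positions)] = g
            col += len(positions)

            hom = g != HET
            hp, hg = positions[hom], g[hom]
            bps, blks = [], []
            if hg.size:
                change = np.flatnonzero(np.diff(hg.astype(np.int16)) != 0)
                run_start = 0
                for j in change:
                    bps.append((int(hp[j]), int(hp[j + 1])))
                    blks.append((int(hg[run_start]), int(hp[run_start]), int(hp[j])))
                    run_start = j + 1
                blks.append((int(hg[run_start]), int(hp[run_start]), int(hp[-1])))
            breakpoints[(line, c.name)] = bps
            blocks[(line, c.name)] = blks

    return RilTruth(mapspec, lines, chroms_arr, pos_arr, geno, breakpoints, blocks)


# ---------------------------------------------------------------------------
# skim observation

def observe_skim(truth: RilTruth, model: SkimObservationModel):
    """Thin true genotypes to skim-coverage parent-coded calls.

    Homozygous sites yield a call with probability ``observation_rate``;
    observed calls are flipped A<->B with probability ``error_rate``.
    Residual heterozygous sites are reported as missing: a skim depth of
    ~0.3x gives at most one read per site, which cannot produce a credible
    homozygous parent call at a heterozygous locus, and the downstream
    window caller has no heterozygous category.
    """
    from .genotypes import ParentCodedGenotypes

    rng = np.random.default_rng(model.seed)
    calls = truth.genotypes.copy()
    observed = rng.random(calls.shape) < model.observation_rate
    flip = rng.random(calls.shape) < model.error_rate
    calls[~observed] = MISSING
    calls[calls == HET] = MISSING
    hom = (calls == A) | (calls == B)
    calls[hom & flip] = np.int8(1) - calls[hom & flip]
    return ParentCodedGenotypes(
        lines=list(truth.lines),
        chroms=truth.chroms.copy(),
        pos=truth.pos.copy(),
        calls=calls,
    )


# ---------------------------------------------------------------------------
# phenotypes

def simulate_phenotypes(truth: RilTruth, model: PhenotypeModel, seed: int) -> pd.DataFrame:
    """Balanced line x environment x replicate phenotypes.

    y = mu + env_effect + sum_q a_q * x_q + g_line + ge_(line,env) + e, with
    x in {-1, 0, +1} for the {A, HET, B} genotype at each planted locus.
    Returns a tidy frame (line, trait, environment, replicate, value).
    """
    rng = np.random.default_rng(seed)
    n = len(truth.lines)
    e, r = model.n_environments, model.n_replicates
    envs = [f"E{j + 1}" for j in range(e)]
    rows = []
    for trait in model.traits:
        genetic = np.full(n, trait.mu)
        for chrom, bp, effect in trait.qtl:
            xi = truth.locus_index(chrom, bp)
            x = np.zeros(n)
            g = truth.genotypes[:, xi]
            x[g == A] = -1.0
            x[g == B] = 1.0
            genetic = genetic + effect * x
        g_res = rng.normal(0.0, np.sqrt(trait.var_g_residual), n)
        ge = rng.normal(0.0, np.sqrt(trait.var_ge), (n, e))
        for j, env in enumerate(envs):
            base = genetic + g_res + ge[:, j] + model.env_effects[j]
            for rep in range(1, r + 1):
                eps = rng.normal(0.0, np.sqrt(trait.var_e), n)
                vals = base + eps
                rows.append(pd.DataFrame({
                    "line": truth.lines, "trait": trait.name, "environment": env,
                    "replicate": rep, "value": vals,
                }))
    if model.mendelian_locus is not None:
        tname, chrom, bp = model.mendelian_locus
        xi = truth.locus_index(chrom, bp)
        vals = (truth.genotypes[:, xi] == B).astype(float)
        for env in envs:
            for rep in range(1, r + 1):
                rows.append(pd.DataFrame({
                    "line": truth.lines, "trait": tname, "environment": env,
                    "replicate": rep, "value": vals,
                }))
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# scenarios

def default_scenario(scale: float = 0.1, n_lines: int = 188, generation: int = 8,
                     seed: int = 0) -> tuple[GeneticMapSpec, PedigreeParams]:
    """Design modeled on a 20-chromosome soybean-like genome: ~91k SNPs at
    full scale, scaled down by ``scale`` (default 10x) for test speed."""
    rng = np.random.default_rng(seed)
    n_chrom = 20
    chroms, positions = [], {}
    total_snps = int(round(91_342 * scale))
    per_chrom = max(2, total_snps // n_chrom)
    for i in range(n_chrom):
        name = str(i + 1)
        length_bp = int(rng.integers(35_000_000, 60_000_000))
        length_cm = float(rng.uniform(80, 140))
        pos = np.sort(rng.choice(np.arange(1, length_bp + 1), size=per_chrom, replace=False))
        chroms.append(ChromSpec(name, length_bp, length_cm))
        positions[name] = pos
    return GeneticMapSpec(chroms, positions), PedigreeParams(n_lines, generation)


def uniform_map(n_chrom: int, n_snps: int, length_bp: int = 40_000_000,
                length_cm: float = 100.0) -> GeneticMapSpec:
    """Evenly spaced SNPs; convenient for tests."""
    chroms, positions = [], {}
    for i in range(n_chrom):
        name = str(i + 1)
        chroms.append(ChromSpec(name, length_bp, length_cm))
        positions[name] = np.linspace(1, length_bp, n_snps, dtype=np.int64)
    return GeneticMapSpec(chroms, positions)


def scenario_from_json(path) -> tuple[GeneticMapSpec, PedigreeParams, SkimObservationModel, PhenotypeModel]:
    """Load a simulation scenario from a JSON config file."""
    with open(path) as fh:
        cfg = json.load(fh)
    chroms = [ChromSpec(str(c["name"]), int(c["length_bp"]), float(c["length_cm"]))
              for c in cfg["chromosomes"]]
    positions = {}
    rng = np.random.default_rng(cfg.get("snp_seed", 0))
    for c, spec in zip(chroms, cfg["chromosomes"]):
        if "snp_positions" in spec:
            positions[c.name] = np.asarray(spec["snp_positions"], dtype=np.int64)
        else:
            n = int(spec["n_snps"])
            positions[c.name] = np.sort(
                rng.choice(np.arange(1, c.length_bp + 1), size=n, replace=False))
    mapspec = GeneticMapSpec(chroms, positions, cfg.get("mapping_function", "kosambi"))
    ped = PedigreeParams(int(cfg["n_lines"]), int(cfg.get("generation", 8)))
    obs = SkimObservationModel(float(cfg.get("observation_rate", 0.3)),
                               float(cfg.get("error_rate", 0.005)),
                               int(cfg.get("observation_seed", 0)))
    traits = [TraitSpec(t["name"], float(t.get("mu", 0.0)),
                        tuple((str(q[0]), int(q[1]), float(q[2])) for q in t.get("qtl", [])),
                        float(t.get("var_g_residual", 0.0)),
                        float(t.get("var_ge", 0.0)), float(t.get("var_e", 0.0)))
              for t in cfg.get("traits", [])]
    mend = cfg.get("mendelian_locus")
    phen = PhenotypeModel(traits,
                          int(cfg.get("n_environments", 1)),
                          int(cfg.get("n_replicates", 1)),
                          cfg.get("env_effects"),
                          (mend[0], str(mend[1]), int(mend[2])) if mend else None)
    return mapspec, ped, obs, phen
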