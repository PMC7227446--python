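"""Synthetic two-company breeding-program data generator.

Emulates the structure of a winter-barley line-testing program run by two
companies: a shared founder pool crossed into full-sib subfamilies plus
singleton crosses, inbred line development by single-seed descent, SNP
genotypes produced by gene dropping with Haldane recombination, an
unbalanced multi-environment (company-year-location) trial design, and
phenotypes drawn from the exact generating model

    y = mu + E + L + g + a + gE + aE + eps

with known variance components, so that every stage of the analysis
pipeline can be validated against known truth.  Defaults reproduce the
scale of the motivating study design: ~900 lines in subfamilies of 2-24
full sibs, ~5,000 SNPs on 7 chromosomes, 14 environments over two companies
and three years, and variance-component magnitudes of a protein-content
analysis (environment variance dominating, small genetic and interaction
variances).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .markers import MarkerMatrix, compute_grm, filter_markers
from .pedigree import PedigreeTable, compute_a_matrix, sort_pedigree
from .phenotypes import PhenotypeTable, make_env_id
from .relmatrix import RelationshipMatrix

#: combined-data protein magnitudes of the most comprehensive model
DEFAULT_TRUTH = {
    "sigma2_E": 0.58, "sigma2_L": 0.02, "sigma2_g": 0.04, "sigma2_a": 0.03,
    "sigma2_gE": 0.01, "sigma2_aE": 0.01, "sigma2_R": 0.10,
}

#: company -> year -> number of locations (14 environments total)
DEFAULT_COMPANIES = {
    "NS": {2015: 3, 2016: 3, 2017: 3},
    "SJ": {2015: 2, 2016: 1, 2017: 2},
}


@dataclass
class SimulationConfig:
    n_founders: int = 60
    n_families: int = 186
    family_size_range: tuple[int, int] = (2, 24)
    n_singleton_crosses: int = 86
    selfing_generations: int = 4
    n_markers: int = 5000
    n_chromosomes: int = 7
    founder_maf_range: tuple[float, float] = (0.1, 0.5)
    companies: dict = field(default_factory=lambda: {c: dict(y) for c, y in DEFAULT_COMPANIES.items()})
    missing_design_fraction: float = 0.55
    mu: float = 10.48
    trait: str = "protein"
    truth: dict = field(default_factory=lambda: dict(DEFAULT_TRUTH))
    additive_mode: str = "independent"  # "independent" | "combined"
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.family_size_range
        if lo > hi:
            raise ValueError("family_size_range inverted")
        if not (0.0 <= self.missing_design_fraction <= 0.9):
            raise ValueError("missing_design_fraction must be in [0, 0.9]")
        if any(v < 0 for v in self.truth.values()):
            raise ValueError("variance components must be >= 0")
        if self.additive_mode not in ("independent", "combined"):
            raise ValueError(f"unknown additive_mode {self.additive_mode!r}")

    def environments(self) -> list[tuple[str, int, int]]:
        out = []
        for company, years in self.companies.items():
            for year, n_loc in sorted(years.items()):
                out += [(company, year, loc) for loc in range(1, n_loc + 1)]
        return out


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    pedigree: PedigreeTable
    markers: MarkerMatrix
    phenotypes: PhenotypeTable
    G: RelationshipMatrix
    A: RelationshipMatrix
    truth: dict

    @property
    def member_lines(self) -> list[str]:
        return self.truth["line_ids"]


def simulate_pedigree(config: SimulationConfig, rng: np.random.Generator | None = None
                      ) -> PedigreeTable:
    """Founders plus biparental crosses into full-sib families and singletons.

    Family sizes are drawn from a shifted geometric distribution clipped to
    ``family_size_range`` (right-skewed, matching typical breeding programs
    where a few crosses carry many sibs).  Parent pairs are distinct
    unordered founder pairs.  The result is topologically ordered.
    """
    if config.n_founders < 2:
        raise ValueError("need at least 2 founders")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    lo, hi = config.family_size_range
    founders = [f"F{i:04d}" for i in range(1, config.n_founders + 1)]

    n_cross = config.n_families + config.n_singleton_crosses
    pairs: list[tuple[str, str]] = []
    used = set()
    while len(pairs) < n_cross:
        i, j = rng.choice(config.n_founders, size=2, replace=False)
        key = (min(i, j), max(i, j))
        if key in used:
            continue
        used.add(key)
        pairs.append((founders[key[0]], founders[key[1]]))

    ids = list(founders)
    p1s: list[str | None] = [None] * len(founders)
    p2s: list[str | None] = [None] * len(founders)
    k = 0
    for fam, (pa, pb) in enumerate(pairs):
        size = 1 if fam >= config.n_families else int(
            np.clip(lo + rng.geometric(0.3) - 1, lo, hi))
        for _ in range(size):
            k += 1
            ids.append(f"L{k:04d}")
            p1s.append(pa)
            p2s.append(pb)
    return sort_pedigree(PedigreeTable(ids, p1s, p2s))


def _gamete(h1: np.ndarray, h2: np.ndarray, chrom_slices, rec_prob,
            rng: np.random.Generator) -> np.ndarray:
    """One recombinant gamete under the Haldane model (1 Morgan/chromosome)."""
    out = np.empty_like(h1)
    for sl, r in zip(chrom_slices, rec_prob):
        m = sl.stop - sl.start
        phase = np.empty(m, dtype=bool)
        phase[0] = rng.random() < 0.5
        if m > 1:
            switches = rng.random(m - 1) < r
            phase[1:] = phase[0] ^ (np.cumsum(switches) % 2).astype(bool)
        out[sl] = np.where(phase, h2[sl], h1[sl])
    return out


def simulate_genotypes(ped: PedigreeTable, config: SimulationConfig,
                       rng: np.random.Generator | None = None) -> MarkerMatrix:
    """Gene-drop SNP genotypes down a sorted pedigree.

    Founder haplotypes are drawn per marker at a frequency uniform in
    ``founder_maf_range``; offspring receive recombinant gametes (uniform
    marker spacing, one Morgan per chromosome); each non-founder line is then
    advanced by ``selfing_generations`` rounds of single-seed descent before
    being genotyped as 0/1/2 dosages.
    """
    if config.n_markers < config.n_chromosomes:
        raise ValueError("need at least one marker per chromosome")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    m = config.n_markers
    bounds = np.linspace(0, m, config.n_chromosomes + 1).astype(int)
    chrom_slices = [slice(a, b) for a, b in zip(bounds[:-1], bounds[1:])]
    rec_prob = [0.5 * (1.0 - np.exp(-2.0 / max(sl.stop - sl.start - 1, 1)))
                for sl in chrom_slices]

    p = rng.uniform(*config.founder_maf_range, size=m)
    haplos: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for lid, p1, p2 in zip(ped.ids, ped.parent1, ped.parent2):
        if p1 is None and p2 is None:
            haplos[lid] = (rng.random(m) < p, rng.random(m) < p)
        else:
            hp1 = haplos[p1 if p1 is not None else p2]
            hp2 = haplos[p2 if p2 is not None else p1]
            h1 = _gamete(*hp1, chrom_slices, rec_prob, rng)
            h2 = _gamete(*hp2, chrom_slices, rec_prob, rng)
            for _ in range(config.selfing_generations):
                h1, h2 = (_gamete(h1, h2, chrom_slices, rec_prob, rng),
                          _gamete(h1, h2, chrom_slices, rec_prob, rng))
            haplos[lid] = (h1, h2)

    geno = np.vstack([(haplos[l][0].astype(np.int8) + haplos[l][1]).astype(float)
                      for l in ped.ids])
    marker_ids = [f"M{j:05d}" for j in range(1, m + 1)]
    return MarkerMatrix(list(ped.ids), marker_ids, geno)


def _psd_draw(K: np.ndarray, scale: float, rng: np.random.Generator) -> np.ndarray:
    """Draw from N(0, K * scale) via truncated eigendecomposition."""
    if scale == 0:
        return np.zeros(len(K))
    w, V = np.linalg.eigh((K + K.T) / 2.0)
    if w[0] < -1e-6 * max(w[-1], 1e-300):
        raise ValueError("supplied kernel not PSD")
    w = np.clip(w, 0.0, None)
    return V @ (np.sqrt(w * scale) * rng.standard_normal(len(w)))


def simulate_phenotypes(lines: list[str], config: SimulationConfig,
                        G: RelationshipMatrix, A: RelationshipMatrix,
                        rng: np.random.Generator | None = None
                        ) -> tuple[PhenotypeTable, dict]:
    """Draw phenotypes from the full interaction model over a trial design.

    Lines are split between the companies (in order, proportionally to each
    company's environment count); each line appears in a random subset of its
    company's environments (each cell kept with probability
    ``1 - missing_design_fraction``, at least one per line).  Every random
    term is drawn from its model distribution: environment and line effects
    iid, genomic and pedigree breeding values from G and A, interaction
    effects per environment from the matching G/A block, residuals iid.

    Returns the phenotype table and a truth dict holding the variance
    components and the per-line genetic values.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    t = config.truth
    envs = [make_env_id(c, y, l) for c, y, l in config.environments()]
    env_meta = {make_env_id(c, y, l): (c, y, l) for c, y, l in config.environments()}
    companies = list(config.companies)
    env_by_company = {c: [e for e in envs if env_meta[e][0] == c] for c in companies}

    lines = [str(l) for l in lines]
    weights = np.array([len(env_by_company[c]) for c in companies], float)
    shares = np.floor(np.cumsum(weights) / weights.sum() * len(lines)).astype(int)
    company_of = {}
    start = 0
    for c, stop in zip(companies, shares):
        for l in lines[start:stop]:
            company_of[l] = c
        start = stop
    for l in lines[start:]:
        company_of[l] = companies[-1]

    keep_p = 1.0 - config.missing_design_fraction
    rows = []
    for l in lines:
        cand = env_by_company[company_of[l]]
        keep = np.where(rng.random(len(cand)) < keep_p)[0]
        if keep.size == 0:
            keep = np.array([rng.integers(len(cand))])
        for i in keep:
            c, y, loc = env_meta[cand[i]]
            rows.append((l, c, y, loc, cand[i]))
    df = pd.DataFrame(rows, columns=["line_id", "company", "year", "location", "env_id"])

    Ksub_g = G.submatrix(lines)
    Ksub_a = A.submatrix(lines)
    line_pos = {l: i for i, l in enumerate(lines)}
    env_pos = {e: i for i, e in enumerate(envs)}

    E = rng.normal(0.0, np.sqrt(t.get("sigma2_E", 0.0)), size=len(envs))
    L = rng.normal(0.0, np.sqrt(t.get("sigma2_L", 0.0)), size=len(lines))
    if config.additive_mode == "independent":
        g = _psd_draw(Ksub_g, t.get("sigma2_g", 0.0), rng)
        a = _psd_draw(Ksub_a, t.get("sigma2_a", 0.0), rng)
    else:
        # one combined additive draw from G carrying the total additive variance
        g = _psd_draw(Ksub_g, t.get("sigma2_g", 0.0) + t.get("sigma2_a", 0.0), rng)
        a = np.zeros(len(lines))

    rl = df["line_id"].map(line_pos).to_numpy()
    re = df["env_id"].map(env_pos).to_numpy()
    y = config.mu + E[re] + L[rl] + g[rl] + a[rl]

    for sym, K in (("sigma2_gE", Ksub_g), ("sigma2_aE", Ksub_a)):
        s2 = t.get(sym, 0.0)
        if s2 == 0:
            continue
        inter = np.zeros(len(df))
        for e in range(len(envs)):
            ridx = np.where(re == e)[0]
            if ridx.size == 0:
                continue
            bl = rl[ridx]
            inter[ridx] = _psd_draw(K[np.ix_(bl, bl)], s2, rng)
        y = y + inter

    y = y + rng.normal(0.0, np.sqrt(t.get("sigma2_R", 0.0)), size=len(df))
    df[config.trait] = y
    table = PhenotypeTable(df, traits=(config.trait,))
    truth = {
        "variance_components": dict(t), "mu": config.mu,
        "line_ids": lines, "g": g, "a": a,
        "company_of": company_of,
        "E": dict(zip(envs, E)),
    }
    return table, truth


def simulate_dataset(config: SimulationConfig | None = None, seed: int | None = None
                     ) -> SyntheticDataset:
    """Full pipeline: pedigree -> genotypes -> G and A -> phenotypes.

    Derives independent RNG streams for each stage from ``seed`` (or
    ``config.seed``), so the whole dataset is reproducible and stages stay
    decoupled.  G is the VanRaden matrix of the gene-dropped markers after
    monomorphic filtering; A is the fully-inbred-rescaled pedigree matrix,
    both restricted to the phenotyped (non-founder) lines.
    """
    config = config or SimulationConfig()
    if seed is not None:
        config = SimulationConfig(**{**config.__dict__, "seed": seed})
    streams = [np.random.default_rng(s)
               for s in np.random.SeedSequence(config.seed).spawn(3)]
    ped = simulate_pedigree(config, streams[0])
    markers_all = simulate_genotypes(ped, config, streams[1])

    members = [l for l, p1, p2 in zip(ped.ids, ped.parent1, ped.parent2)
               if p1 is not None or p2 is not None]
    midx = [markers_all.line_ids.index(l) for l in members]
    markers = MarkerMatrix(members, markers_all.marker_ids,
                           markers_all.genotypes[midx])
    markers, _ = filter_markers(markers)
    G = compute_grm(markers)
    A = compute_a_matrix(ped, assume_fully_inbred=True, member_ids=members)

    phenotypes, truth = simulate_phenotypes(members, config, G, A, streams[2])
    return SyntheticDataset(config, ped, markers, phenotypes, G, A, truth)
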