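"""Multi-kernel Bayesian mixed models with genotype-by-environment interaction.

The phenotype of line j in environment i is modelled as

    y_ij = mu + E_i + L_j + g_j + a_j + gE_ij + aE_ij + e_ij

where E (environment) and L (line, i.e. non-additive residual genetic) are
iid random effects, g is the genomic breeding value with covariance G*sg2
(G = VanRaden genomic relationship matrix), a is the pedigree breeding value
with covariance A*sa2, and the interaction terms have record-level
covariances given by Hadamard products, e.g. Cov(gE) = (Zg G Zg') o (Ze Ze')
* sgE2.  Six standard model variants (ELG, ELG-GxE, ELA, ELA-AxE, ELGA,
ELGA-GxE-AxE) select subsets of these terms.

Fitting is by Gibbs sampling.  Each random term is rotated once into the
eigenbasis of its record-level kernel; in that basis the effect coordinates
are conditionally independent normals, so a full update costs two
matrix-vector products per term per iteration.  Variances get scaled
inverse-chi-square updates; fixed effects (intercept, optionally a breeding
program / company covariate) get a flat prior.

The Hadamard interaction kernel is exactly block-diagonal over environments
(the environment incidence product zeroes every cross-environment entry), so
its eigenbasis is computed per environment block and stored sparse.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, sparse

from .phenotypes import PhenotypeTable
from .relmatrix import RelationshipMatrix

log = logging.getLogger(__name__)

#: random-term composition of the six named models
MODEL_TERMS: dict[str, tuple[str, ...]] = {
    "ELG": ("E", "L", "g"),
    "ELG-GxE": ("E", "L", "g", "gE"),
    "ELA": ("E", "L", "a"),
    "ELA-AxE": ("E", "L", "a", "aE"),
    "ELGA": ("E", "L", "g", "a"),
    "ELGA-GxE-AxE": ("E", "L", "g", "a", "gE", "aE"),
}

VAR_SYMBOL = {"E": "sigma2_E", "L": "sigma2_L", "g": "sigma2_g", "a": "sigma2_a",
              "gE": "sigma2_gE", "aE": "sigma2_aE"}

_EIG_TOL = 1e-8  # relative eigenvalue truncation for rank-deficient kernels


def _ensure_env_id(df: pd.DataFrame) -> pd.DataFrame:
    if "env_id" in df.columns:
        return df
    from .phenotypes import make_env_id
    return df.assign(env_id=[make_env_id(c, y, l) for c, y, l in
                             zip(df["company"], df["year"], df["location"])])


@dataclass
class ModelSpec:
    """Declarative description of one mixed model and its MCMC settings."""

    name: str
    terms: tuple[str, ...] = ()
    fixed: tuple[str, ...] = ("intercept",)
    n_iter: int = 12_000
    burn_in: int = 2_000
    thin: int = 5
    seed: int = 0
    prior_df: float = 5.0
    prior_r2: float = 0.5  # share of phenotypic variance assigned to the priors

    def __post_init__(self) -> None:
        if not self.terms:
            if self.name not in MODEL_TERMS:
                raise ValueError(f"unknown model {self.name!r}; expected one of {list(MODEL_TERMS)}")
            self.terms = MODEL_TERMS[self.name]
        if "gE" in self.terms and "g" not in self.terms:
            raise ValueError("gE requires g")
        if "aE" in self.terms and "a" not in self.terms:
            raise ValueError("aE requires a")
        if "intercept" not in self.fixed:
            self.fixed = ("intercept", *self.fixed)
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")

    def with_fixed(self, *extra: str) -> "ModelSpec":
        fixed = tuple(dict.fromkeys((*self.fixed, *extra)))
        return ModelSpec(self.name, self.terms, fixed, self.n_iter, self.burn_in,
                         self.thin, self.seed, self.prior_df, self.prior_r2)

    def replace(self, **kw) -> "ModelSpec":
        d = dict(name=self.name, terms=self.terms, fixed=self.fixed,
                 n_iter=self.n_iter, burn_in=self.burn_in, thin=self.thin,
                 seed=self.seed, prior_df=self.prior_df, prior_r2=self.prior_r2)
        d.update(kw)
        return ModelSpec(**d)


@dataclass
class KernelTerm:
    """A random term bound to the eigenbasis of its record-level kernel.

    ``U`` (records x rank, dense or sparse CSR) has orthonormal columns and
    ``d`` holds the corresponding eigenvalues, so the record kernel is
    ``U diag(d) U'``.  Metadata (level ids, per-environment blocks) supports
    mapping record effects back to levels and kernel-regression prediction.
    """

    name: str
    U: object
    d: np.ndarray
    level_ids: list[str] | None = None       # for E, L, g, a
    record_level: np.ndarray | None = None   # record -> level index
    blocks: list[dict] | None = None         # for gE/aE: per-env metadata

    @property
    def var_symbol(self) -> str:
        return VAR_SYMBOL[self.name]

    @property
    def rank(self) -> int:
        return len(self.d)

    def record_kernel(self) -> np.ndarray:
        """Materialize the dense records x records covariance (tests/QA)."""
        U = self.U.toarray() if sparse.issparse(self.U) else self.U
        return (U * self.d) @ U.T

    def mean_diag(self) -> float:
        n = self.U.shape[0]
        return float(np.sum(self.d)) / n


def _orth_indicator(codes: np.ndarray, n_levels: int) -> tuple[np.ndarray, np.ndarray]:
    """Eigenbasis of Z Z' for an incidence matrix Z: normalized indicator
    columns with eigenvalues equal to level record counts."""
    n = len(codes)
    counts = np.bincount(codes, minlength=n_levels).astype(float)
    keep = counts > 0
    cols = np.cumsum(keep) - 1
    U = sparse.csr_matrix(
        (1.0 / np.sqrt(counts[codes]), (np.arange(n), cols[codes])),
        shape=(n, int(keep.sum())),
    )
    return U, counts[keep]


def _psd_factor(K: np.ndarray, tol: float = _EIG_TOL) -> tuple[np.ndarray, np.ndarray]:
    """Truncated eigendecomposition of a PSD matrix; raises if K is
    meaningfully non-PSD."""
    K = (K + K.T) / 2.0
    w, V = np.linalg.eigh(K)
    top = max(w[-1], 0.0)
    if top <= 0:
        raise ValueError("kernel has no positive eigenvalue")
    if w[0] < -1e-6 * top:
        raise ValueError(f"kernel not PSD (min eig {w[0]:.3g} vs max {top:.3g})")
    keep = w > tol * top
    return w[keep], V[:, keep]


def build_kernels(table: PhenotypeTable | pd.DataFrame, spec: ModelSpec,
                  G: RelationshipMatrix | None = None,
                  A: RelationshipMatrix | None = None) -> list[KernelTerm]:
    """Construct the record-level covariance kernels for a model.

    Main terms get kernel Z K Z' (K identity for E and L, G or A for the
    breeding-value terms); interaction terms get the Hadamard product of the
    genetic record kernel with the environment incidence product, built
    block-wise per environment.
    """
    df = _ensure_env_id(table.df if isinstance(table, PhenotypeTable) else table)
    if df[["line_id", "env_id"]].duplicated().any():
        raise ValueError("duplicate (line, environment) records; average them first")
    lines = list(dict.fromkeys(df["line_id"]))
    envs = list(dict.fromkeys(df["env_id"]))
    line_idx = {l: i for i, l in enumerate(lines)}
    env_idx = {e: i for i, e in enumerate(envs)}
    rec_line = df["line_id"].map(line_idx).to_numpy()
    rec_env = df["env_id"].map(env_idx).to_numpy()

    genetic = {"g": G, "a": A}
    factors: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}

    terms: list[KernelTerm] = []
    for name in spec.terms:
        if name in ("E", "L"):
            codes = rec_env if name == "E" else rec_line
            n_lev = len(envs) if name == "E" else len(lines)
            U, d = _orth_indicator(codes, n_lev)
            terms.append(KernelTerm(name, U, d,
                                    level_ids=envs if name == "E" else lines,
                                    record_level=codes))
        elif name in ("g", "a"):
            R = genetic[name]
            if R is None:
                raise ValueError(f"model {spec.name!r} needs a "
                                 f"{'genomic' if name == 'g' else 'pedigree'} matrix")
            missing = [l for l in lines if l not in R]
            if missing:
                raise KeyError(f"lines absent from {R.kind} matrix: {missing[:5]}"
                               + ("..." if len(missing) > 5 else ""))
            K = R.submatrix(lines)
            w, V = _psd_factor(K)
            factors[name] = (K, w, V)
            B = (V * np.sqrt(w))[rec_line]          # records x rank, ZKZ' = BB'
            Ub, s, _ = np.linalg.svd(B, full_matrices=False)
            keep = s > np.sqrt(_EIG_TOL) * s[0]
            terms.append(KernelTerm(name, Ub[:, keep], s[keep] ** 2,
                                    level_ids=lines, record_level=rec_line))
        elif name in ("gE", "aE"):
            gname = name[0]
            R = genetic[gname]
            K = factors[gname][0] if gname in factors else R.submatrix(lines)
            rows, cols, vals, dlist, blocks = [], [], [], [], []
            offset = 0
            for e in range(len(envs)):
                ridx = np.where(rec_env == e)[0]
                bl = rec_line[ridx]
                Kb = K[np.ix_(bl, bl)]
                w, V = _psd_factor(Kb)
                r = len(w)
                rows.append(np.repeat(ridx, r))
                cols.append(np.tile(np.arange(offset, offset + r), len(ridx)))
                vals.append(V.ravel())
                dlist.append(w)
                blocks.append({"env": envs[e], "records": ridx,
                               "line_idx": bl, "K": Kb})
                offset += r
            U = sparse.csr_matrix(
                (np.concatenate(vals),
                 (np.concatenate(rows), np.concatenate(cols))),
                shape=(len(df), offset),
            )
            terms.append(KernelTerm(name, U, np.concatenate(dlist), blocks=blocks))
        else:
            raise ValueError(f"unknown term {name!r}")
    return terms


def _design_matrix(df: pd.DataFrame, fixed: tuple[str, ...]) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(df))]
    names = ["intercept"]
    for f in fixed:
        if f == "intercept":
            continue
        levels = sorted(df[f].astype(str).unique())
        for lev in levels[1:]:  # first level is the reference
            cols.append((df[f].astype(str) == lev).to_numpy(float))
            names.append(f"{f}[{lev}]")
    return np.column_stack(cols), names


@dataclass
class FitResult:
    """Posterior summaries of one model fit plus what prediction needs."""

    spec: ModelSpec
    trait: str
    fixed_names: list[str]
    beta_mean: np.ndarray
    beta_sd: np.ndarray
    varcomp: dict[str, float]
    varcomp_sd: dict[str, float]
    variance_samples: dict[str, np.ndarray]
    record_effects: dict[str, np.ndarray]
    kernels: list[KernelTerm]
    records: pd.DataFrame
    y: np.ndarray
    n_retained: int
    G: RelationshipMatrix | None = None
    A: RelationshipMatrix | None = None
    effect_samples: dict[str, np.ndarray] | None = None
    _pred_cache: dict = field(default_factory=dict, repr=False)

    @property
    def mu(self) -> float:
        return float(self.beta_mean[0])

    def level_effects(self, term: str) -> pd.Series:
        """Posterior-mean effect per level (environment or line) of a main term."""
        kt = next(k for k in self.kernels if k.name == term)
        if kt.level_ids is None:
            raise ValueError(f"{term!r} is not a level-indexed main term")
        u = self.record_effects[term]
        sums = np.bincount(kt.record_level, weights=u, minlength=len(kt.level_ids))
        counts = np.bincount(kt.record_level, minlength=len(kt.level_ids)).astype(float)
        observed = counts > 0
        vals = np.zeros(len(kt.level_ids))
        vals[observed] = sums[observed] / counts[observed]
        return pd.Series(vals, index=pd.Index(kt.level_ids, name="level"), name=term)

    def summary_frame(self) -> pd.DataFrame:
        rows = [{"component": k, "posterior_mean": v, "posterior_sd": self.varcomp_sd[k]}
                for k, v in self.varcomp.items()]
        return pd.DataFrame(rows)


def fit_gibbs(table: PhenotypeTable | pd.DataFrame, trait: str, spec: ModelSpec,
              kernels: list[KernelTerm],
              fix_variances: dict[str, float] | None = None,
              collect_effects: bool = False) -> FitResult:
    """Fit one model by Gibbs sampling.

    ``fix_variances`` maps variance symbols (e.g. ``sigma2_g``, ``sigma2_R``)
    to values that are held fixed instead of sampled — used for validation
    against direct generalized-least-squares solutions.

    Priors are scaled inverse-chi-square with ``spec.prior_df`` degrees of
    freedom; each term's scale is set so the prior mode corresponds to an
    equal share of ``prior_r2`` times the sample phenotypic variance
    (normalized by the kernel's mean diagonal), the convention of standard
    Bayesian genomic-prediction software.
    """
    df = _ensure_env_id(table.df if isinstance(table, PhenotypeTable) else table)
    y = df[trait].to_numpy(float)
    if np.isnan(y).any():
        raise ValueError("missing trait values present; subset records first")
    n = len(y)
    if n < 30:
        raise ValueError(f"need >= 30 records, got {n}")
    fix_variances = dict(fix_variances or {})

    W, fixed_names = _design_matrix(df, spec.fixed)
    WtW = W.T @ W
    cho = linalg.cho_factor(WtW)
    Lw = np.linalg.cholesky(np.linalg.inv(WtW))

    rng = np.random.default_rng(spec.seed)
    vary = float(np.var(y, ddof=1))
    df0 = spec.prior_df
    nt = len(kernels)
    S0 = {}
    for kt in kernels:
        mode = spec.prior_r2 * vary / nt / max(kt.mean_diag(), 1e-12)
        S0[kt.var_symbol] = mode * (df0 + 2.0) / df0
    mode_r = (1.0 - spec.prior_r2) * vary
    S0["sigma2_R"] = mode_r * (df0 + 2.0) / df0

    # state
    sig2 = {kt.var_symbol: fix_variances.get(kt.var_symbol, df0 * S0[kt.var_symbol] / (df0 + 2))
            for kt in kernels}
    sig2_R = fix_variances.get("sigma2_R", df0 * S0["sigma2_R"] / (df0 + 2))
    beta = linalg.cho_solve(cho, W.T @ y)
    delta = {kt.name: np.zeros(kt.rank) for kt in kernels}
    u = {kt.name: np.zeros(n) for kt in kernels}
    e = y - W @ beta

    n_keep = (spec.n_iter - spec.burn_in) // spec.thin
    beta_samps = np.empty((n_keep, len(beta)))
    var_samps = {kt.var_symbol: np.empty(n_keep) for kt in kernels}
    var_samps["sigma2_R"] = np.empty(n_keep)
    u_sum = {kt.name: np.zeros(n) for kt in kernels}
    u_samps = {kt.name: np.empty((n_keep, n)) for kt in kernels} if collect_effects else None

    kept = 0
    for it in range(spec.n_iter):
        # fixed effects, flat prior
        r = e + W @ beta
        bmean = linalg.cho_solve(cho, W.T @ r)
        beta = bmean + np.sqrt(sig2_R) * (Lw @ rng.standard_normal(len(beta)))
        e = r - W @ beta

        # random terms in their eigenbases
        for kt in kernels:
            s2 = sig2[kt.var_symbol]
            r_t = e + u[kt.name]
            z = kt.U.T @ r_t
            prec = 1.0 / sig2_R + 1.0 / (kt.d * s2)
            mean = z / sig2_R / prec
            dlt = mean + rng.standard_normal(kt.rank) / np.sqrt(prec)
            delta[kt.name] = dlt
            u_new = kt.U @ dlt
            u[kt.name] = u_new
            e = r_t - u_new
            if kt.name in ("E", "L"):
                # recentering move: shift the term mean into the intercept.
                # For identity-kernel terms the eigenvalues are the level
                # record counts and level effects are delta/sqrt(d); the
                # conditional for the shift c is N(mean(level effects),
                # sigma2_term / n_levels).  Likelihood is untouched (mu + c
                # compensates), so the posterior is preserved while breaking
                # the slow intercept/term-mean random walk.
                lev = dlt / np.sqrt(kt.d)
                c = rng.normal(lev.mean(), np.sqrt(s2 / kt.rank))
                dlt = dlt - c * np.sqrt(kt.d)
                delta[kt.name] = dlt
                u[kt.name] = u[kt.name] - c
                beta[0] += c  # residual unchanged: the shift cancels
            if kt.var_symbol not in fix_variances:
                ss = float(np.sum(dlt * dlt / kt.d))
                sig2[kt.var_symbol] = (df0 * S0[kt.var_symbol] + ss) / rng.chisquare(df0 + kt.rank)

        if "sigma2_R" not in fix_variances:
            sig2_R = (df0 * S0["sigma2_R"] + float(e @ e)) / rng.chisquare(df0 + n)
        if not np.isfinite(sig2_R) or sig2_R > 1e12 * max(vary, 1e-300):
            raise RuntimeError(f"divergent chain at iteration {it}: sigma2_R={sig2_R:.3g}")

        if it >= spec.burn_in and (it - spec.burn_in) % spec.thin == 0 and kept < n_keep:
            beta_samps[kept] = beta
            for kt in kernels:
                var_samps[kt.var_symbol][kept] = sig2[kt.var_symbol]
                u_sum[kt.name] += u[kt.name]
                if u_samps is not None:
                    u_samps[kt.name][kept] = u[kt.name]
            var_samps["sigma2_R"][kept] = sig2_R
            kept += 1

    record_effects = {name: s / kept for name, s in u_sum.items()}
    varcomp = {sym: float(v[:kept].mean()) for sym, v in var_samps.items()}
    varcomp_sd = {sym: float(v[:kept].std(ddof=1)) for sym, v in var_samps.items()}
    return FitResult(
        spec=spec, trait=trait, fixed_names=fixed_names,
        beta_mean=beta_samps[:kept].mean(axis=0), beta_sd=beta_samps[:kept].std(axis=0, ddof=1),
        varcomp=varcomp, varcomp_sd=varcomp_sd,
        variance_samples={k: v[:kept] for k, v in var_samps.items()},
        record_effects=record_effects, kernels=kernels,
        records=df.reset_index(drop=True), y=y, n_retained=kept,
        effect_samples={k: v[:kept] for k, v in u_samps.items()} if u_samps else None,
    )


def fit_model(table: PhenotypeTable, trait: str, spec: ModelSpec,
              G: RelationshipMatrix | None = None,
              A: RelationshipMatrix | None = None,
              fix_variances: dict[str, float] | None = None) -> FitResult:
    """Filter to non-missing records of `trait`, build kernels, run the sampler."""
    df = table.records_for_trait(trait) if isinstance(table, PhenotypeTable) else table
    dup = df.duplicated(["line_id", "env_id"])
    if dup.any():
        log.warning("averaging %d duplicate (line, environment) record(s)", int(dup.sum()))
        keys = [c for c in ("line_id", "company", "year", "location", "env_id") if c in df.columns]
        df = df.groupby(keys, as_index=False, sort=False)[trait].mean()
    kernels = build_kernels(df, spec, G=G, A=A)
    fit = fit_gibbs(df, trait, spec, kernels, fix_variances=fix_variances)
    fit.G, fit.A = G, A
    return fit


# -- prediction -------------------------------------------------------------

def _pinv_apply(K: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Moore-Penrose solve K x = v via truncated eigendecomposition."""
    w, V = np.linalg.eigh((K + K.T) / 2.0)
    keep = w > _EIG_TOL * max(w[-1], 1e-300)
    return V[:, keep] @ ((V[:, keep].T @ v) / w[keep])


def _genetic_weights(fit: FitResult, term: str) -> tuple[list[str], np.ndarray]:
    """Cache t = K_train^+ ghat_train for kernel-regression prediction."""
    key = ("main", term)
    if key not in fit._pred_cache:
        R = fit.G if term == "g" else fit.A
        kt = next(k for k in fit.kernels if k.name == term)
        lines = kt.level_ids
        ghat = fit.level_effects(term).to_numpy()
        K = R.submatrix(lines)
        fit._pred_cache[key] = (lines, _pinv_apply(K, ghat))
    return fit._pred_cache[key]


def _interaction_weights(fit: FitResult, term: str) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    key = ("inter", term)
    if key not in fit._pred_cache:
        kt = next(k for k in fit.kernels if k.name == term)
        u = fit.record_effects[term]
        out = {}
        for bl in kt.blocks:
            out[bl["env"]] = (bl["line_idx"], _pinv_apply(bl["K"], u[bl["records"]]))
        fit._pred_cache[key] = out
    return fit._pred_cache[key]


def predict_values(fit: FitResult, targets, mode: str = "breeding_value") -> np.ndarray:
    """Predict target (line, environment) pairs from a fitted model.

    ``breeding_value`` mode returns khat = ghat + ahat (whichever additive
    terms the model contains), extending to unphenotyped lines by kernel
    regression ghat_new = G(new, train) G(train, train)^+ ghat_train.
    ``breeding_value_interaction`` adds the genetic-by-environment
    interaction contributions for environments seen in training (zero for
    unobserved environments) — the composition used to rank lines within
    known environments without crediting the environment mean itself.
    ``full`` further adds the environment main effect and the line effect
    for trained levels; unobserved levels contribute zero.
    """
    if mode not in ("breeding_value", "breeding_value_interaction", "full"):
        raise ValueError(f"unknown prediction mode {mode!r}")
    targets = list(targets)
    t_lines = [str(l) for l, _ in targets]
    t_envs = [str(e) for _, e in targets]
    term_names = {kt.name for kt in fit.kernels}

    pred = np.zeros(len(targets))
    for term in ("g", "a"):
        if term not in term_names:
            continue
        R = fit.G if term == "g" else fit.A
        if R is None:
            raise ValueError(f"fit lacks the relationship matrix for {term!r}")
        absent = [l for l in t_lines if l not in R]
        if absent:
            raise KeyError(f"target line(s) absent from {R.kind} matrix: {absent[:5]}")
        train_lines, t_w = _genetic_weights(fit, term)
        Kx = R.submatrix(t_lines, train_lines)
        pred += Kx @ t_w

    if mode in ("breeding_value_interaction", "full"):
        if mode == "full":
            if "E" in term_names:
                Ehat = fit.level_effects("E")
                pred += np.array([Ehat.get(e, 0.0) for e in t_envs])
            if "L" in term_names:
                Lhat = fit.level_effects("L")
                pred += np.array([Lhat.get(l, 0.0) for l in t_lines])
        for term in ("gE", "aE"):
            if term not in term_names:
                continue
            R = fit.G if term == "gE" else fit.A
            weights = _interaction_weights(fit, term)
            train_line_ids = next(k for k in fit.kernels if k.name == term[0]).level_ids
            for i, (l, env) in enumerate(zip(t_lines, t_envs)):
                if env not in weights:
                    continue
                bl_lines, t_w = weights[env]
                kx = R.submatrix([l], [train_line_ids[j] for j in bl_lines])[0]
                pred[i] += float(kx @ t_w)
    return pred


# -- derived summaries -------------------------------------------------------

def variance_partition(fit: FitResult) -> dict[str, float]:
    """Percent of within-environment variance per random term (E excluded).

    Each non-environment variance component (including the residual) is
    expressed as a percentage of their sum; the percentages add to 100.
    """
    comps = {k: v for k, v in fit.varcomp.items() if k != "sigma2_E"}
    total = sum(comps.values())
    if total <= 0:
        raise ValueError("no positive non-environment variance")
    return {k: 100.0 * v / total for k, v in comps.items()}


def partition_additive(fit_or_sigma_g, sigma_a: float | None = None) -> tuple[float, float]:
    """Split total additive variance into genomic and pedigree fractions.

    Accepts either a FitResult containing both g and a terms, or the two
    variance components directly.  Returns (VR_G, VR_A) with
    VR_G = sg2 / (sg2 + sa2) and VR_A = 1 - VR_G.
    """
    if isinstance(fit_or_sigma_g, FitResult):
        vc = fit_or_sigma_g.varcomp
        if "sigma2_g" not in vc or "sigma2_a" not in vc:
            raise ValueError("fit must contain both genomic and pedigree terms")
        sg, sa = vc["sigma2_g"], vc["sigma2_a"]
    else:
        sg, sa = float(fit_or_sigma_g), float(sigma_a)
    tot = sg + sa
    if tot <= 0:
        raise ValueError("total additive variance is zero")
    vr_g = sg / tot
    return vr_g, 1.0 - vr_g


@dataclass
class HeritabilityEstimate:
    H2: float
    h2: float
    sigma2_y: float
    mh: float
    ph: float
    n_genotypes: int


def estimate_heritability(fit: FitResult, table: PhenotypeTable | None = None,
                          plot_counts: dict[str, float] | None = None
                          ) -> HeritabilityEstimate:
    """Broad- and narrow-sense heritability for unbalanced data.

        H2 = (sL2 + sg2 + sa2) / sy2,   h2 = (sg2 + sa2) / sy2,
        sy2 = sL2 + sg2 + sa2 + sgE2/mh + saE2/mh + sR2/ph,

    with mh and ph the harmonic means over genotypes of, respectively, the
    number of environments and the number of plots per genotype.  The line
    variance is part of the phenotypic variance (omitting it could push H2
    above 1).  Variance components absent from the model contribute zero.
    Without plot-level counts, a genotype's plot count defaults to its
    record count (one plot per line-environment record).
    """
    vc = fit.varcomp
    sL = vc.get("sigma2_L", 0.0)
    sg = vc.get("sigma2_g", 0.0)
    sa = vc.get("sigma2_a", 0.0)
    sgE = vc.get("sigma2_gE", 0.0)
    saE = vc.get("sigma2_aE", 0.0)
    sR = vc["sigma2_R"]

    df = (table.df if isinstance(table, PhenotypeTable) else table) \
        if table is not None else fit.records
    m = df.groupby("line_id")["env_id"].nunique()
    m = m[m > 0]
    n = len(m)
    mh = n / float(np.sum(1.0 / m.to_numpy(float)))
    if plot_counts is None:
        p = df.groupby("line_id").size().reindex(m.index).to_numpy(float)
    else:
        p = np.array([plot_counts[l] for l in m.index], float)
    ph = n / float(np.sum(1.0 / p))

    sy2 = sL + sg + sa + sgE / mh + saE / mh + sR / ph
    return HeritabilityEstimate(
        H2=(sL + sg + sa) / sy2,
        h2=(sg + sa) / sy2,
        sigma2_y=sy2, mh=mh, ph=ph, n_genotypes=n,
    )
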