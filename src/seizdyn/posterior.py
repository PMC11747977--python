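"""Bayesian multilevel models of bifurcation-morphology prevalence.

Onset classes (SN/SubH reference, SNIC, SupH) follow a categorical
logistic regression; offsets reduce to a Bernoulli model of SNIC/SH vs
FLC (the rare SupH offsets are excluded before fitting).  Fixed effects
cover the seizure-level covariates (vigilance, classification,
standardized length) and patient-level covariates (age, gender, lobe,
etiology); patients contribute random intercepts.  Intercept priors are
anchored at the logit of the overall class prevalence, so deviations from
the pooled distribution require evidence; coefficient priors are
Normal(0, 1.5) and random-intercept scales Half-Normal(1).

Sampling uses Hamiltonian Monte Carlo with closed-form gradients of the
joint log-density, a dual-averaged step size and a diagonal mass matrix
adapted during warmup.  Each configured chain starts from a random
overdispersed offset around the posterior mode.  Convergence is checked
with split R-hat across chains (arviz) and a posterior predictive check
on the class frequencies.
Posterior contrasts between two levels of a clinical factor marginalize
the predicted class probability over the empirical distribution of every
other covariate and summarize the difference draws by median, MAP (KDE
mode), 95% equal-tailed credible interval, probability of direction (pd)
and the fraction of mass inside the region of practical equivalence
(ROPE, default half-width 10% of the minority-class prevalence).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

ONSET_CLASSES = ("SN/SubH", "SNIC", "SupH")
OFFSET_CLASSES = ("FLC", "SNIC/SH")

_DEFAULT_COVARIATES = (
    "vigilance", "classification", "length_s", "age", "gender", "lobe", "etiology",
)
_REFERENCES = {
    "vigilance": "Awake",
    "classification": "FIAS",
    "gender": "female",
    "lobe": "temporal",
    "etiology": "hippocampal sclerosis",
}
_NUMERIC = ("length_s", "age")


@dataclass
class McmcConfig:
    chains: int = 6
    iterations: int = 6000
    warmup: int = 2000
    seed: int = 0

    def __post_init__(self):
        if not self.warmup < self.iterations:
            raise ValueError("warmup must be smaller than iterations")


@dataclass
class Design:
    """Fixed-effect design with reproducible level coding."""

    columns: list[str]
    spec: list[tuple]  # (covariate, kind, info)

    @classmethod
    def from_records(cls, records: pd.DataFrame, covariates) -> "Design":
        spec = []
        columns = []
        for cov in covariates:
            if cov not in records.columns:
                continue
            if cov in _NUMERIC:
                vals = records[cov].astype(float)
                sd = float(vals.std())
                if sd <= 0:
                    continue
                spec.append((cov, "numeric", (float(vals.mean()), sd)))
                columns.append(cov)
            else:
                levels = sorted(records[cov].astype(str).unique())
                if len(levels) < 2:
                    continue
                ref = _REFERENCES.get(cov, levels[0])
                if ref not in levels:
                    ref = levels[0]
                others = [l for l in levels if l != ref]
                spec.append((cov, "categorical", (ref, others)))
                columns.extend(f"{cov}[{l}]" for l in others)
        return cls(columns=columns, spec=spec)

    def matrix(self, records: pd.DataFrame, override: dict | None = None) -> np.ndarray:
        cols = []
        for cov, kind, info in self.spec:
            if override and cov in override:
                vals = pd.Series([override[cov]] * len(records), index=records.index)
            else:
                vals = records[cov]
            if kind == "numeric":
                mean, sd = info
                cols.append((vals.astype(float).to_numpy() - mean) / sd)
            else:
                _, others = info
                v = vals.astype(str).to_numpy()
                for level in others:
                    cols.append((v == level).astype(float))
        if not cols:
            return np.zeros((len(records), 0))
        return np.column_stack(cols)


@dataclass
class PosteriorSamples:
    draws: np.ndarray  # chains x draws x n_params
    param_names: list[str]
    side: str
    classes: tuple
    design: Design
    records: pd.DataFrame
    patient_index: np.ndarray
    patients: np.ndarray
    config: McmcConfig
    random_intercept: bool
    prevalence: np.ndarray
    acceptance_fraction: float = np.nan

    @property
    def flat(self) -> np.ndarray:
        return self.draws.reshape(-1, self.draws.shape[-1])

    def by_name(self, name: str) -> np.ndarray:
        return self.flat[:, self.param_names.index(name)]


@dataclass
class Diagnostics:
    rhat: pd.Series
    max_rhat: float
    pp_check: pd.DataFrame  # class, observed, mean, low, high, inside
    ok: bool
    notes: list[str] = field(default_factory=list)


@dataclass
class ContrastSummary:
    side: str
    bifm_class: str
    factor: str
    level_a: str
    level_b: str
    median: float
    map: float
    ci_low: float
    ci_high: float
    pd: float
    rope: float
    rope_halfwidth: float
    n_draws: int


def _pack_names(classes, design_cols, patients, random_intercept):
    names = []
    for k in classes[1:]:
        names.append(f"alpha[{k}]")
        names.extend(f"beta[{k}]:{c}" for c in design_cols)
        if random_intercept:
            names.append(f"log_sigma[{k}]")
            names.extend(f"z[{k}]:{p}" for p in patients)
    return names


class _LogProb:
    """Vectorized posterior log-density over an array of parameter vectors."""

    def __init__(self, y, X, patient_index, n_patients, n_logit,
                 anchor, random_intercept, beta_sd=1.5, alpha_sd=1.0):
        self.y = y  # class index per row, 0 = reference
        self.X = X
        self.pidx = patient_index
        self.n_pat = n_patients
        self.K = n_logit  # number of non-reference classes
        self.P = X.shape[1]
        self.anchor = anchor  # prior centers for the intercepts
        self.re = random_intercept
        self.beta_sd = beta_sd
        self.alpha_sd = alpha_sd
        self.block = 1 + self.P + (1 + self.n_pat if random_intercept else 0)
        self.ndim = self.K * self.block

    def unpack(self, theta):
        theta = np.atleast_2d(theta)
        W = theta.shape[0]
        alpha = np.empty((W, self.K))
        beta = np.empty((W, self.K, self.P))
        sigma = np.zeros((W, self.K))
        z = np.zeros((W, self.K, self.n_pat))
        for k in range(self.K):
            off = k * self.block
            alpha[:, k] = theta[:, off]
            beta[:, k] = theta[:, off + 1 : off + 1 + self.P]
            if self.re:
                sigma[:, k] = np.exp(np.clip(theta[:, off + 1 + self.P], -30.0, 30.0))
                z[:, k] = theta[:, off + 2 + self.P :][:, : self.n_pat]
        return alpha, beta, sigma, z

    def eta(self, alpha, beta, sigma, z, X=None, pidx=None):
        X = self.X if X is None else X
        pidx = self.pidx if pidx is None else pidx
        # (W, K, n)
        e = alpha[:, :, None] + np.einsum("wkp,np->wkn", beta, X)
        if self.re:
            e = e + (sigma[:, :, None] * z)[:, :, pidx]
        return e

    def value_and_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        """Posterior log-density and its gradient for one parameter vector."""
        alpha, beta, sigma, z = (a[0] for a in self.unpack(theta[None, :]))
        eta = alpha[:, None] + beta @ self.X.T  # (K, n)
        if self.re:
            eta = eta + (sigma[:, None] * z)[:, self.pidx]
        full = np.vstack([np.zeros(eta.shape[1]), eta])  # (K+1, n)
        m = full.max(axis=0)
        ex = np.exp(full - m)
        lse = m + np.log(ex.sum(axis=0))
        p = ex / ex.sum(axis=0)
        n = self.y.size
        loglik = float(full[self.y, np.arange(n)].sum() - lse.sum())
        onehot = np.zeros_like(full)
        onehot[self.y, np.arange(n)] = 1.0
        g = (onehot - p)[1:]  # (K, n), d loglik / d eta_k

        d_alpha = g.sum(axis=1) - (alpha - self.anchor) / self.alpha_sd**2
        d_beta = g @ self.X - beta / self.beta_sd**2
        lp_val = (
            loglik
            - 0.5 * float((((alpha - self.anchor) / self.alpha_sd) ** 2).sum())
            - 0.5 * float(((beta / self.beta_sd) ** 2).sum())
        )
        grad = np.empty_like(theta)
        for k in range(self.K):
            off = k * self.block
            grad[off] = d_alpha[k]
            grad[off + 1 : off + 1 + self.P] = d_beta[k]
        if self.re:
            for k in range(self.K):
                off = k * self.block
                gsum = np.bincount(self.pidx, weights=g[k], minlength=self.n_pat)
                grad[off + 1 + self.P] = (
                    sigma[k] * float((g[k] * z[k, self.pidx]).sum()) + 1.0 - sigma[k] ** 2
                )
                grad[off + 2 + self.P : off + 2 + self.P + self.n_pat] = (
                    sigma[k] * gsum - z[k]
                )
            lp_val += float((-0.5 * sigma**2 + np.log(sigma)).sum())
            lp_val += float((-0.5 * z**2).sum())
        return lp_val, grad

    def __call__(self, theta):
        theta = np.atleast_2d(theta)
        alpha, beta, sigma, z = self.unpack(theta)
        e = self.eta(alpha, beta, sigma, z)  # (W, K, n)
        W, K, n = e.shape
        full = np.concatenate([np.zeros((W, 1, n)), e], axis=1)  # ref logit 0
        lse = np.log(np.exp(full - full.max(axis=1, keepdims=True)).sum(axis=1))
        lse += full.max(axis=1)
        yidx = np.broadcast_to(self.y[None, None, :], (W, 1, n))
        chosen = np.take_along_axis(full, yidx, axis=1)[:, 0, :]
        loglik = (chosen - lse).sum(axis=1)
        # priors
        lp = -0.5 * ((alpha - self.anchor[None, :]) / self.alpha_sd) ** 2
        lp = lp.sum(axis=1)
        lp += (-0.5 * (beta / self.beta_sd) ** 2).sum(axis=(1, 2))
        if self.re:
            # sigma ~ HalfNormal(1) sampled as log sigma (Jacobian = +log sigma)
            lp += (-0.5 * sigma**2 + np.log(sigma)).sum(axis=1)
            lp += (-0.5 * z**2).sum(axis=(1, 2))
        out = loglik + lp
        return out if theta.shape[0] > 1 else out[0]


def _prepare(records: pd.DataFrame, side: str, covariates):
    records = records.copy()
    if side == "onset":
        classes = ONSET_CLASSES
    elif side == "offset":
        classes = OFFSET_CLASSES
        records = records[records.bifm != "SupH"]
    else:
        raise ValueError(f"side must be onset/offset, got {side!r}")
    records = records[records.bifm.isin(classes)].reset_index(drop=True)
    if records.empty:
        raise ValueError(f"no records with a resolved {side} class")
    y = np.array([classes.index(b) for b in records.bifm])
    design = Design.from_records(
        records, covariates if covariates is not None else _DEFAULT_COVARIATES
    )
    X = design.matrix(records)
    patients, pidx = np.unique(records.patient_id, return_inverse=True)
    counts = np.bincount(y, minlength=len(classes)).astype(float)
    counts = np.maximum(counts, 0.5)
    prevalence = counts / counts.sum()
    anchor = np.log(prevalence[1:] / prevalence[0])
    return records, classes, y, design, X, patients, pidx, prevalence, anchor


def _hmc_chain(
    lp: _LogProb,
    q0: np.ndarray,
    n_warmup: int,
    n_draws: int,
    rng: np.random.Generator,
    max_leapfrog: int = 64,
    target_accept: float = 0.8,
) -> tuple[np.ndarray, float]:
    """One Hamiltonian Monte Carlo chain with dual-averaged step size and
    diagonal mass adaptation during warmup.  Returns (draws, accept rate)."""
    ndim = q0.size
    q = q0.copy()
    val, grad = lp.value_and_grad(q)
    eps = 0.1
    mu = np.log(10 * eps)
    log_eps_bar, h_bar = 0.0, 0.0
    gamma, t0, kappa = 0.05, 10.0, 0.75
    inv_mass = np.ones(ndim)
    warm_qs = []
    draws = np.empty((n_draws, ndim))
    n_accept, n_total = 0, 0
    for it in range(n_warmup + n_draws):
        p = rng.standard_normal(ndim) / np.sqrt(inv_mass)
        L = int(rng.integers(max(1, int(0.8 * max_leapfrog)), max_leapfrog + 1))
        q_new, g_new = q.copy(), grad.copy()
        p_new = p + 0.5 * eps * g_new
        diverged = False
        for _ in range(L):
            q_new = q_new + eps * inv_mass * p_new
            v_new, g_new = lp.value_and_grad(q_new)
            if not np.isfinite(v_new):
                diverged = True
                break
            p_new = p_new + eps * g_new
        if not diverged:
            p_new = p_new - 0.5 * eps * g_new  # undo the extra half step
            h0 = -val + 0.5 * float((p**2 * inv_mass).sum())
            h1 = -v_new + 0.5 * float((p_new**2 * inv_mass).sum())
            log_alpha = min(0.0, h0 - h1)
            accept_prob = float(np.exp(log_alpha))
        else:
            accept_prob = 0.0
        if not diverged and np.log(rng.random()) < log_alpha:
            q, val, grad = q_new, v_new, g_new
            n_accept += 1
        n_total += 1
        if it < n_warmup:
            # dual averaging toward the target acceptance rate
            m = it + 1
            h_bar = (1 - 1 / (m + t0)) * h_bar + (target_accept - accept_prob) / (m + t0)
            log_eps = mu - np.sqrt(m) / gamma * h_bar
            w = m**-kappa
            log_eps_bar = w * log_eps + (1 - w) * log_eps_bar
            eps = float(np.exp(log_eps))
            if n_warmup // 3 <= it < 2 * n_warmup // 3:
                warm_qs.append(q.copy())
            if it == 2 * n_warmup // 3 and len(warm_qs) > 10:
                var = np.var(np.asarray(warm_qs), axis=0)
                inv_mass = np.maximum(var, 1e-6)
            if it == n_warmup - 1:
                eps = float(np.exp(log_eps_bar))
        else:
            draws[it - n_warmup] = q
    return draws, n_accept / max(n_total, 1)


def fit_bifm_model(
    records: pd.DataFrame,
    side: str,
    mcmc_config: McmcConfig | None = None,
    covariates=None,
    random_intercept: bool = True,
) -> PosteriorSamples:
    """Fit the prevalence model for one side and return posterior draws.

    ``records`` needs one row per seizure-side with a resolved class
    (columns: patient_id, bifm, plus any covariates used).  Offset rows
    with a SupH class are excluded before fitting.  Each configured chain
    is an independent HMC run started from a random overdispersed offset
    around the posterior mode; per chain, ``warmup`` adaptation steps are
    discarded and ``iterations - warmup`` draws returned.
    """
    config = mcmc_config or McmcConfig()
    records, classes, y, design, X, patients, pidx, prevalence, anchor = _prepare(
        records, side, covariates
    )
    if patients.size < 2:
        raise ValueError("need at least 2 patients")
    use_re = random_intercept and patients.size >= 3
    lp = _LogProb(y, X, pidx, patients.size, len(classes) - 1, anchor, use_re)

    # posterior mode for initialization
    x0 = np.zeros(lp.ndim)
    for k in range(lp.K):
        x0[k * lp.block] = anchor[k]
        if use_re:
            x0[k * lp.block + 1 + lp.P] = -1.0  # log sigma
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = optimize.minimize(
            lambda th: (-(vg := lp.value_and_grad(th))[0], -vg[1]),
            x0, jac=True, method="L-BFGS-B", options={"maxiter": 500},
        )
    mode = res.x

    need = config.iterations - config.warmup
    rng_master = np.random.default_rng(config.seed)
    chain_draws = []
    acc = []
    for c in range(config.chains):
        rng = np.random.default_rng(int(rng_master.integers(0, 2**31 - 1)))
        q0 = mode + rng.normal(0, 0.25, size=lp.ndim)
        draws_c, a = _hmc_chain(lp, q0, config.warmup, need, rng)
        chain_draws.append(draws_c)
        acc.append(a)
    draws = np.stack(chain_draws)  # chains x need x ndim
    names = _pack_names(classes, design.columns, patients, use_re)
    return PosteriorSamples(
        draws=draws,
        param_names=names,
        side=side,
        classes=classes,
        design=design,
        records=records,
        patient_index=pidx,
        patients=patients,
        config=config,
        random_intercept=use_re,
        prevalence=prevalence,
        acceptance_fraction=float(np.mean(acc)),
    )


def class_probabilities(
    posterior: PosteriorSamples,
    override: dict | None = None,
    max_draws: int = 2000,
) -> np.ndarray:
    """Marginal predicted class probabilities per draw.

    Predicted probabilities are averaged over the empirical distribution of
    the observed covariates (with ``override`` forcing chosen factors to a
    level), including each row's patient intercept.  Returns an array of
    shape (draws, n_classes).
    """
    lp = _make_lp(posterior)
    flat = posterior.flat
    if flat.shape[0] > max_draws:
        idx = np.linspace(0, flat.shape[0] - 1, max_draws).astype(int)
        flat = flat[idx]
    alpha, beta, sigma, z = lp.unpack(flat)
    X = posterior.design.matrix(posterior.records, override=override)
    e = lp.eta(alpha, beta, sigma, z, X=X)  # (S, K, n)
    S, K, n = e.shape
    full = np.concatenate([np.zeros((S, 1, n)), e], axis=1)
    full -= full.max(axis=1, keepdims=True)
    p = np.exp(full)
    p /= p.sum(axis=1, keepdims=True)
    return p.mean(axis=2).reshape(S, K + 1)


def _make_lp(posterior: PosteriorSamples) -> _LogProb:
    records = posterior.records
    y = np.array([posterior.classes.index(b) for b in records.bifm])
    X = posterior.design.matrix(records)
    anchor = np.log(posterior.prevalence[1:] / posterior.prevalence[0])
    return _LogProb(
        y, X, posterior.patient_index, posterior.patients.size,
        len(posterior.classes) - 1, anchor, posterior.random_intercept,
    )


def diagnostics(posterior: PosteriorSamples, pp_draws: int = 500) -> Diagnostics:
    """Split R-hat per parameter plus a posterior predictive check on the
    class frequencies (observed vs 95% interval of replicated)."""
    import arviz as az

    if posterior.draws.shape[0] < 2:
        return Diagnostics(
            rhat=pd.Series(dtype=float), max_rhat=np.nan,
            pp_check=pd.DataFrame(), ok=False,
            notes=["single chain: R-hat unavailable"],
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ds = az.convert_to_dataset(posterior.draws[:, :, :])
        r = az.rhat(ds)["x"].to_numpy()
    rhat = pd.Series(r, index=posterior.param_names)
    max_rhat = float(np.nanmax(r))

    # posterior predictive: replicate class draws under the observed design
    lp = _make_lp(posterior)
    flat = posterior.flat
    idx = np.linspace(0, flat.shape[0] - 1, min(pp_draws, flat.shape[0])).astype(int)
    alpha, beta, sigma, z = lp.unpack(flat[idx])
    e = lp.eta(alpha, beta, sigma, z)
    S, K, n = e.shape
    full = np.concatenate([np.zeros((S, 1, n)), e], axis=1)
    full -= full.max(axis=1, keepdims=True)
    p = np.exp(full)
    p /= p.sum(axis=1, keepdims=True)  # (S, K+1, n)
    rng = np.random.default_rng(posterior.config.seed + 99)
    u = rng.random((S, n))
    cum = np.cumsum(p, axis=1)
    y_rep = (u[:, None, :] < cum).argmax(axis=1)  # (S, n)
    rows = []
    y_obs = np.array([posterior.classes.index(b) for b in posterior.records.bifm])
    for k, cls in enumerate(posterior.classes):
        freq_rep = (y_rep == k).mean(axis=1)
        lo, hi = np.quantile(freq_rep, [0.025, 0.975])
        obs = float((y_obs == k).mean())
        rows.append(
            {"class": cls, "observed": obs, "mean": float(freq_rep.mean()),
             "low": float(lo), "high": float(hi), "inside": bool(lo <= obs <= hi)}
        )
    pp = pd.DataFrame(rows)
    ok = max_rhat <= 1.01 and bool(pp.inside.all())
    notes = []
    if max_rhat > 1.01:
        notes.append(f"poor mixing: max R-hat {max_rhat:.3f} > 1.01")
    if not pp.inside.all():
        notes.append("posterior predictive interval misses an observed frequency")
    return Diagnostics(rhat=rhat, max_rhat=max_rhat, pp_check=pp, ok=ok, notes=notes)


def contrast(
    posterior: PosteriorSamples,
    factor: str,
    level_a: str,
    level_b: str,
    bifm_class: str,
    rope_halfwidth: float | None = None,
    max_draws: int = 2000,
) -> ContrastSummary:
    """Posterior difference in one class's probability between two levels.

    Per draw, the class probability is computed with ``factor`` forced to
    ``level_a`` and to ``level_b`` (all other covariates kept at their
    observed empirical distribution) and differenced.  pd is the fraction
    of the difference draws sharing the sign of the median; the ROPE
    half-width defaults to 10% of the overall minority-class prevalence.
    """
    if bifm_class not in posterior.classes:
        raise ValueError(f"{bifm_class!r} not a class of the {posterior.side} model")
    cov_names = [c for c, _, _ in posterior.design.spec]
    if factor not in cov_names:
        raise ValueError(f"factor {factor!r} not in the fitted design {cov_names}")
    for lv in (level_a, level_b):
        _, kind, info = next(s for s in posterior.design.spec if s[0] == factor)
        if kind == "categorical" and lv not in ([info[0]] + list(info[1])):
            raise ValueError(f"level {lv!r} unknown for factor {factor!r}")
    k = posterior.classes.index(bifm_class)
    pa = class_probabilities(posterior, {factor: level_a}, max_draws)[:, k]
    pb = class_probabilities(posterior, {factor: level_b}, max_draws)[:, k]
    return summarize_difference(
        pa - pb, posterior, factor, level_a, level_b, bifm_class, rope_halfwidth
    )


def summarize_difference(
    diff: np.ndarray,
    posterior: PosteriorSamples | None = None,
    factor: str = "",
    level_a: str = "",
    level_b: str = "",
    bifm_class: str = "",
    rope_halfwidth: float | None = None,
) -> ContrastSummary:
    """Median / MAP / 95% CI / pd / ROPE for an array of difference draws."""
    diff = np.asarray(diff, dtype=float)
    med = float(np.median(diff))
    ci_low, ci_high = (float(q) for q in np.quantile(diff, [0.025, 0.975]))
    if np.ptp(diff) > 0:
        kde = stats.gaussian_kde(diff)
        grid = np.linspace(diff.min(), diff.max(), 512)
        map_est = float(grid[np.argmax(kde(grid))])
    else:
        map_est = med
    sign = np.sign(med) if med != 0 else 1.0
    pd_val = float(np.mean(np.sign(diff) == sign)) if med != 0 else 0.5
    pd_val = max(pd_val, 0.5)
    if rope_halfwidth is None:
        if posterior is not None:
            minority = float(posterior.prevalence.min())
        else:
            minority = 0.5
        rope_halfwidth = 0.10 * minority
    rope = float(np.mean(np.abs(diff) <= rope_halfwidth))
    return ContrastSummary(
        side=posterior.side if posterior is not None else "",
        bifm_class=bifm_class,
        factor=factor,
        level_a=level_a,
        level_b=level_b,
        median=med,
        map=map_est,
        ci_low=ci_low,
        ci_high=ci_high,
        pd=pd_val,
        rope=rope,
        rope_halfwidth=float(rope_halfwidth),
        n_draws=diff.size,
    )
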