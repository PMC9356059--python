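"""Group-level inference on ROI response amplitudes.

Three linear mixed-effects analyses run on the tidy response table, all
with simple-coded (each level vs. reference, centered) categorical factors,
standardized amplitudes, and a random intercept per participant:

* cross-language model — Amplitude ~ Frequency + Group +
  Frequency x Group + (1 | Participant) on the pooled speech voices at 5
  and 10 Hz, with pairwise group contrasts at each frequency and frequency
  contrasts within groups;
* speech vs. non-speech model — Amplitude ~ Frequency * Group * Stimulus +
  (1 | Participant) on the unfamiliar-language voice and its vocoded
  control, followed by per-frequency sub-models;
* harmonic regression — each participant's 10 Hz response modelled on
  Group plus their 5 Hz response, probing whether the 10 Hz response is
  just a harmonic of the 5 Hz one.

REML estimation is delegated to statsmodels' MixedLM; fixed-effect
covariances, Satterthwaite degrees of freedom and omnibus F tests are
computed here from the closed-form random-intercept GLS algebra (the
multi-df denominator follows the eigencontrast construction used by
lmerTest).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import config as cfg
from .config import StatsConfig

__all__ = ["LMEResult", "Model2Result", "make_response_table", "fit_lme",
           "fit_model1", "fit_model2", "harmonic_check"]


# ---------------------------------------------------------------------------
# Design-matrix helpers (simple coding)
# ---------------------------------------------------------------------------

def _simple_codes(levels: list[str]) -> dict[str, np.ndarray]:
    """Simple coding: level j vs. reference (levels[0]), centered.

    Each non-reference level gets a column equal to (k-1)/k for that level
    and -1/k elsewhere, so the intercept is the mean of cell means and each
    beta is a level-minus-reference difference.
    """
    k = len(levels)
    codes = {}
    for j, lev in enumerate(levels):
        row = np.full(k - 1, -1.0 / k)
        if j > 0:
            row[j - 1] += 1.0
        codes[lev] = row
    return codes


@dataclass
class _Design:
    factors: dict[str, list[str]]         #: factor -> ordered levels
    terms: dict[str, list[int]]           #: term -> column indices
    colnames: list[str]
    X: np.ndarray

    def cell_row(self, **levels) -> np.ndarray:
        """Design row of the cell mean at the given factor levels."""
        return _design_rows(pd.DataFrame([levels]), self.factors,
                            list(self.terms))[0][0]


def _design_rows(df: pd.DataFrame, factors: dict[str, list[str]],
                 term_names: list[str]):
    codes = {f: _simple_codes(lv) for f, lv in factors.items()}
    parts: list[np.ndarray] = [np.ones((len(df), 1))]
    colnames = ["Intercept"]
    terms = {"Intercept": [0]}
    col = 1
    for term in term_names:
        if term == "Intercept":
            continue
        facs = term.split(":")
        mats = []
        for f in facs:
            mats.append(np.stack([codes[f][v] for v in df[f]]))
        m = mats[0]
        for other in mats[1:]:
            m = np.einsum("ni,nj->nij", m, other).reshape(len(df), -1)
        parts.append(m)
        labels = [[f"{f}[{lv}]" for lv in factors[f][1:]] for f in facs]
        from itertools import product
        names = [":".join(combo) for combo in product(*labels)]
        colnames.extend(names)
        terms[term] = list(range(col, col + m.shape[1]))
        col += m.shape[1]
    return np.hstack(parts), colnames, terms


def _make_design(df: pd.DataFrame, factors: dict[str, list[str]],
                 term_names: list[str]) -> _Design:
    for f, lv in factors.items():
        present = set(df[f])
        missing = [l for l in lv if l not in present]
        if missing:
            raise ValueError(f"factor {f!r} is missing level(s) {missing}")
    X, colnames, terms = _design_rows(df, factors, term_names)
    return _Design(factors=factors, terms=terms, colnames=colnames, X=X)


# ---------------------------------------------------------------------------
# Random-intercept GLS algebra and Satterthwaite df
# ---------------------------------------------------------------------------

class _RandomInterceptModel:
    """Closed-form GLS quantities for y = X b + Z u + e with scalar
    random intercepts per participant group."""

    def __init__(self, y: np.ndarray, X: np.ndarray, groups: np.ndarray):
        self.y, self.X = np.asarray(y, float), np.asarray(X, float)
        self.labels, self.gidx = np.unique(groups, return_inverse=True)
        self.n, self.p = X.shape
        g = self.labels.size
        # sufficient statistics: everything below is O(G p^2) per evaluation
        self.SXX = self.X.T @ self.X
        self.Xty = self.X.T @ self.y
        self.yty = float(self.y @ self.y)
        self.X1 = np.zeros((g, self.p))       # per-group column sums of X
        np.add.at(self.X1, self.gidx, self.X)
        self.Y1 = np.bincount(self.gidx, weights=self.y, minlength=g)
        self.ng = np.bincount(self.gidx, minlength=g).astype(float)

    def _lam(self, s2b: float, s2e: float) -> np.ndarray:
        return s2b / (s2e + self.ng * s2b)

    def beta_cov(self, s2b: float, s2e: float):
        """GLS beta-hat and its covariance at the given variance params."""
        lam = self._lam(s2b, s2e)
        XtViX = (self.SXX - self.X1.T @ (lam[:, None] * self.X1)) / s2e
        XtViy = (self.Xty - self.X1.T @ (lam * self.Y1)) / s2e
        C = np.linalg.inv(XtViX)
        return C @ XtViy, C

    def reml_loglike(self, s2b: float, s2e: float) -> float:
        lam = self._lam(s2b, s2e)
        beta, C = self.beta_cov(s2b, s2e)
        logdetV = float(np.sum((self.ng - 1) * np.log(s2e)
                               + np.log(s2e + self.ng * s2b)))
        u = self.Y1 - self.X1 @ beta          # per-group residual sums
        rss = self.yty - 2 * beta @ self.Xty + beta @ self.SXX @ beta
        quad = (rss - float(lam @ u ** 2)) / s2e
        sign, logdetXX = np.linalg.slogdet(np.linalg.inv(C))
        return -0.5 * ((self.n - self.p) * np.log(2 * np.pi) + logdetV
                       + logdetXX + quad)

    def theta_cov(self, s2b: float, s2e: float) -> np.ndarray:
        """Asymptotic covariance of (s2b, s2e): inverse observed REML
        information (numerical Hessian)."""
        th = np.array([max(s2b, 1e-10), max(s2e, 1e-10)])
        h = np.maximum(1e-7, 1e-4 * th)

        def f(t):
            return self.reml_loglike(max(t[0], 1e-12), max(t[1], 1e-12))

        H = np.zeros((2, 2))
        for i in range(2):
            for j in range(i, 2):
                ei = np.eye(2)[i] * h[i]
                ej = np.eye(2)[j] * h[j]
                H[i, j] = (f(th + ei + ej) - f(th + ei - ej)
                           - f(th - ei + ej) + f(th - ei - ej)) \
                    / (4 * h[i] * h[j])
                H[j, i] = H[i, j]
        return np.linalg.inv(-H)

    def satterthwaite_df(self, c: np.ndarray, s2b: float, s2e: float,
                         theta_cov: np.ndarray) -> float:
        """df = 2 v^2 / Var(v) for v = Var(c' beta-hat)."""
        th = np.array([max(s2b, 0.0), max(s2e, 1e-10)])
        h = np.maximum(1e-7, 1e-4 * np.maximum(th, 1e-6))

        def v(t):
            _, C = self.beta_cov(max(t[0], 1e-12), max(t[1], 1e-12))
            return float(c @ C @ c)

        g = np.zeros(2)
        for i in range(2):
            e = np.eye(2)[i] * h[i]
            g[i] = (v(th + e) - v(th - e)) / (2 * h[i])
        denom = float(g @ theta_cov @ g)
        if denom <= 0:
            return float(self.n - self.p)
        df = 2.0 * v(th) ** 2 / denom
        return float(np.clip(df, 1.0, 1e7))


# ---------------------------------------------------------------------------
# Results containers
# ---------------------------------------------------------------------------

@dataclass
class LMEResult:
    formula: str
    fixed_effects: pd.DataFrame     #: term, beta, se, t, df, p, ci bounds
    anova: pd.DataFrame             #: term, F, df_num, df_den, p
    contrasts: pd.DataFrame
    sigma2_participant: float
    sigma2_residual: float
    n_obs: int
    n_participants: int
    scale_mean: float               #: amplitude standardization offset
    scale_sd: float
    converged: bool = True
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "formula": self.formula,
            "fixed_effects": self.fixed_effects.to_dict("records"),
            "anova": self.anova.to_dict("records"),
            "contrasts": self.contrasts.to_dict("records"),
            "sigma2_participant": self.sigma2_participant,
            "sigma2_residual": self.sigma2_residual,
            "n_obs": self.n_obs, "n_participants": self.n_participants,
            "scale_mean": self.scale_mean, "scale_sd": self.scale_sd,
            "converged": self.converged, "extra": self.extra,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, default=float)


@dataclass
class Model2Result:
    full: LMEResult            #: three-way model (2a)
    per_frequency: dict[str, LMEResult]    #: "5 Hz" (2b), "10 Hz" (2c)


# ---------------------------------------------------------------------------
# Table preparation and core fitting
# ---------------------------------------------------------------------------

FREQ_LABELS = {cfg.SYLLABLE_HZ: "5 Hz", cfg.MORA_HZ: "10 Hz"}


def make_response_table(responses: pd.DataFrame,
                        freqs=(cfg.SYLLABLE_HZ, cfg.MORA_HZ)) -> pd.DataFrame:
    """Tidy analysis table from the ROI-response table (5 and 10 Hz rows)."""
    t = responses[responses["freq_hz"].isin(freqs)].copy()
    t["frequency"] = t["freq_hz"].map(FREQ_LABELS)
    return t[["participant", "group", "condition", "frequency",
              "amplitude_uv"]].reset_index(drop=True)


def _standardize(y: np.ndarray) -> tuple[np.ndarray, float, float]:
    mu, sd = float(np.mean(y)), float(np.std(y, ddof=1))
    if sd == 0:
        raise ValueError("amplitude has zero variance; cannot standardize")
    return (y - mu) / sd, mu, sd


def fit_lme(df: pd.DataFrame, factors: dict[str, list[str]],
            term_names: list[str], contrast_spec, formula: str,
            covariate: str | None = None,
            config: StatsConfig | None = None) -> LMEResult:
    """Fit a random-intercept LME with simple-coded factors.

    ``contrast_spec`` is a list of (name, cell_kwargs_a, cell_kwargs_b)
    whose estimate is the difference of the two cell means; ``covariate``
    optionally appends a standardized continuous regressor.
    """
    from statsmodels.regression.mixed_linear_model import MixedLM

    config = config or StatsConfig()
    participants = df["participant"].to_numpy()
    if np.unique(participants).size < 2:
        raise ValueError("need at least two participants for a random "
                         "intercept model")
    y, mu, sd = _standardize(df["amplitude_uv"].to_numpy(float))
    design = _make_design(df, factors, term_names)
    X = design.X
    colnames = list(design.colnames)
    cov_mu = cov_sd = None
    if covariate is not None:
        c_raw = df[covariate].to_numpy(float)
        cov_mu, cov_sd = float(c_raw.mean()), float(c_raw.std(ddof=0))
        if cov_sd == 0:
            raise ValueError(f"covariate {covariate!r} has zero variance")
        X = np.column_stack([X, (c_raw - cov_mu) / cov_sd])
        colnames.append(covariate)
        design.terms[covariate] = [X.shape[1] - 1]

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mod = MixedLM(y, X, groups=participants)
        converged = True
        try:
            res = mod.fit(reml=True)
            s2e = float(res.scale)
            s2b = float(np.asarray(res.cov_re)[0, 0])
            converged = bool(res.converged)
        except Exception:
            s2e = float(np.var(y)) or 1.0
            s2b = 0.0
            converged = False

    rim = _RandomInterceptModel(y, X, participants)
    s2b = max(s2b, 1e-10)
    s2e = max(s2e, 1e-10)
    beta, C = rim.beta_cov(s2b, s2e)
    try:
        th_cov = rim.theta_cov(s2b, s2e)
    except np.linalg.LinAlgError:
        th_cov = None

    def df_for(c: np.ndarray) -> float:
        if th_cov is None:
            return float(rim.n - rim.p)
        return rim.satterthwaite_df(c, s2b, s2e, th_cov)

    def t_row(name: str, c: np.ndarray) -> dict:
        est = float(c @ beta)
        se = float(np.sqrt(c @ C @ c))
        dfree = df_for(c)
        t = est / se if se > 0 else np.nan
        p = 2 * sps.t.sf(abs(t), dfree) if se > 0 else np.nan
        ci = sps.t.ppf(0.975, dfree) * se
        return dict(term=name, beta=est, se=se, t=t, df=dfree, p=p,
                    ci_low=est - ci, ci_high=est + ci)

    fixed = pd.DataFrame([t_row(nm, np.eye(X.shape[1])[i])
                          for i, nm in enumerate(colnames)])

    # omnibus F per term (Satterthwaite denominator via eigencontrasts)
    anova_rows = []
    for term, cols in design.terms.items():
        if term == "Intercept":
            continue
        L = np.eye(X.shape[1])[cols]
        q = L.shape[0]
        M = L @ C @ L.T
        Fstat = float((L @ beta) @ np.linalg.solve(M, L @ beta)) / q
        evals, evecs = np.linalg.eigh(M)
        nus = []
        for i in range(q):
            ci = evecs[:, i] @ L
            nus.append(df_for(ci))
        nus = np.array(nus)
        good = nus > 2
        if good.any():
            E = float(np.sum(nus[good] / (nus[good] - 2)))
            df_den = 2 * E / (E - q) if E > q else float(rim.n - rim.p)
        else:
            df_den = float(rim.n - rim.p)
        p = sps.f.sf(Fstat, q, df_den)
        anova_rows.append(dict(term=term, F=Fstat, df_num=q,
                               df_den=df_den, p=p))
    anova = pd.DataFrame(anova_rows)

    contrasts = pd.DataFrame([
        t_row(name, design.cell_row(**cell_a) - design.cell_row(**cell_b))
        for name, cell_a, cell_b in (contrast_spec or [])])

    extra = {}
    if covariate is not None:
        extra["covariate_mean"] = cov_mu
        extra["covariate_sd"] = cov_sd
        # slope on the raw (micro-volt) scale
        extra["raw_slope"] = float(
            fixed.loc[fixed.term == covariate, "beta"].iloc[0]
            * sd / cov_sd)
    return LMEResult(formula=formula, fixed_effects=fixed, anova=anova,
                     contrasts=contrasts, sigma2_participant=s2b,
                     sigma2_residual=s2e, n_obs=rim.n,
                     n_participants=int(np.unique(participants).size),
                     scale_mean=mu, scale_sd=sd, converged=converged,
                     extra=extra)


# ---------------------------------------------------------------------------
# The three analyses
# ---------------------------------------------------------------------------

GROUP_LEVELS = list(cfg.GROUPS)
FREQ_LEVELS = ["5 Hz", "10 Hz"]


def fit_model1(table: pd.DataFrame,
               config: StatsConfig | None = None) -> LMEResult:
    """Cross-language comparison on the pooled speech voices."""
    t = table[table["condition"].isin(cfg.SPEECH_CONDITIONS)
              & table["frequency"].isin(FREQ_LEVELS)].copy()
    if t.empty:
        raise ValueError("no speech-voice rows at 5/10 Hz in the table")
    factors = {"frequency": FREQ_LEVELS, "group": GROUP_LEVELS}
    terms = ["frequency", "group", "frequency:group"]
    pairs = [("french", "english"), ("french", "japanese"),
             ("english", "japanese")]
    spec = []
    for fr in FREQ_LEVELS:
        for a, b in pairs:
            spec.append((f"{a}-{b} @ {fr}",
                         dict(frequency=fr, group=a),
                         dict(frequency=fr, group=b)))
    for g in GROUP_LEVELS:
        spec.append((f"5 Hz-10 Hz @ {g}",
                     dict(frequency="5 Hz", group=g),
                     dict(frequency="10 Hz", group=g)))
    return fit_lme(t, factors, terms, spec,
                   "Amplitude ~ Frequency + Group + Frequency:Group "
                   "+ (1 | Participant)", config=config)


def _stimulus_column(t: pd.DataFrame) -> pd.Series:
    return np.where(t["condition"] == "vocoded", "nonspeech",
                    "speech")


def fit_model2(table: pd.DataFrame,
               config: StatsConfig | None = None) -> Model2Result:
    """Speech vs. non-speech (unfamiliar voice vs. vocoded control)."""
    t = table[table["condition"].isin(["polish", "vocoded"])
              & table["frequency"].isin(FREQ_LEVELS)].copy()
    if t.empty:
        raise ValueError("no polish/vocoded rows at 5/10 Hz in the table")
    t["stimulus"] = _stimulus_column(t)
    factors = {"frequency": FREQ_LEVELS, "group": GROUP_LEVELS,
               "stimulus": ["speech", "nonspeech"]}
    terms = ["frequency", "group", "stimulus", "frequency:group",
             "frequency:stimulus", "group:stimulus",
             "frequency:group:stimulus"]
    full = fit_lme(t, factors, terms, [],
                   "Amplitude ~ Frequency * Group * Stimulus "
                   "+ (1 | Participant)", config=config)
    per_freq = {}
    for fr in FREQ_LEVELS:
        sub = t[t["frequency"] == fr]
        sub_factors = {"group": GROUP_LEVELS,
                       "stimulus": ["speech", "nonspeech"]}
        sub_terms = ["group", "stimulus", "group:stimulus"]
        spec = [(f"speech-nonspeech @ {g}",
                 dict(group=g, stimulus="speech"),
                 dict(group=g, stimulus="nonspeech"))
                for g in GROUP_LEVELS]
        spec += [(f"{a}-{b}",
                  dict(group=a, stimulus="speech"),
                  dict(group=b, stimulus="speech"))
                 for a, b in [("french", "english"), ("french", "japanese"),
                              ("english", "japanese")]]
        per_freq[fr] = fit_lme(
            sub, sub_factors, sub_terms, spec,
            f"Amplitude ~ Group + Stimulus + Group:Stimulus "
            f"+ (1 | Participant)   [{fr}]", config=config)
    return Model2Result(full=full, per_frequency=per_freq)


def harmonic_check(table: pd.DataFrame,
                   config: StatsConfig | None = None) -> LMEResult:
    """Is the 10 Hz speech response just a harmonic of the 5 Hz one?

    Regresses the 10 Hz amplitude on Group and the participant's 5 Hz
    amplitude (matched by participant x condition over the speech voices)
    with a random intercept per participant.  ``extra["raw_slope"]`` is the
    5 Hz slope back on the micro-volt scale.
    """
    t = table[table["condition"].isin(cfg.SPEECH_CONDITIONS)].copy()
    a5 = t[t["frequency"] == "5 Hz"].set_index(["participant", "condition"])
    a10 = t[t["frequency"] == "10 Hz"].set_index(["participant", "condition"])
    if not a5.index.equals(a10.index.sortlevel()[0]) and \
            set(a5.index) != set(a10.index):
        raise ValueError("5 and 10 Hz rows are not matched by "
                         "participant x condition")
    merged = a10[["group", "amplitude_uv"]].join(
        a5[["amplitude_uv"]], rsuffix="_5hz", how="inner").reset_index()
    if len(merged) != len(a10):
        raise ValueError("5 and 10 Hz rows are not matched by "
                         "participant x condition")
    return fit_lme(merged, {"group": GROUP_LEVELS}, ["group"], [],
                   "Amplitude10 ~ Group + Amplitude5 + (1 | Participant)",
                   covariate="amplitude_uv_5hz", config=config)
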