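"""Synthetic paired GWAS summary statistics with known causal structure.

The generator works at the summary-statistics level (no individual genotypes):
for variant j with effect-allele frequency EAF_j ~ Uniform(0.05, 0.95), the
standard error of a marginal per-allele effect in a GWAS of N samples is
approximated by se_j = 1 / sqrt(2 N EAF_j (1 - EAF_j)), the standardized-trait
form.  True instruments receive exposure effects gamma_j ~ Normal(gamma_mean,
gamma_sd^2); a configurable fraction of them is invalid, carrying a direct
(pleiotropic) effect alpha_j ~ Normal(alpha_mean, alpha_sd^2) on the outcome in
violation of the exclusion assumption (balanced when alpha_mean = 0,
directional otherwise; alpha is drawn independently of gamma, so the InSIDE
assumption holds by construction).  The true outcome effect of a variant is
theta * gamma_j + alpha_j, with theta the causal effect of the exposure on the
outcome (log-odds scale for a binary outcome).

LD is block-diagonal AR(1): within a block the signed allelic correlation
between adjacent variants is ld_rho, so r^2 decays as ld_rho^(2|i-j|).  Each
true instrument sits at the head of its own block; its LD partners inherit a
proportionally attenuated marginal effect and correlated estimation noise, so
significance-plus-clumping behaves as it does on real data.  Palindromic
variants (A/T, C/G) and outcome-side allele-order swaps are injected with
configurable probabilities to exercise harmonization.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from .instruments import LDMatrix
from .sumstats import CANONICAL_COLUMNS, SummaryStats, harmonize

_NONPALINDROMIC_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                         ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]

#: base-pair spacing between adjacent variants in a block
_WITHIN_BLOCK_BP = 5_000
#: base-pair spacing between block starts on the same chromosome; far outside
#: the default 10,000 kb clumping window so blocks never clump across
_BLOCK_OFFSET_BP = 100_000_000


@dataclass
class SimulationConfig:
    """Study conditions for one simulated exposure/outcome pair.

    Defaults emulate the GWAS sizes of the screening study this package
    models: a continuous white-matter connectivity exposure measured in 26,333
    individuals and a binary Alzheimer's-disease outcome of 85,844 samples,
    with 30 independent instruments of realistic strength (per-SNP F mostly in
    the tens to low hundreds) and no pleiotropy unless configured.
    """

    m_variants: int = 300
    n_blocks: int = 60
    ld_rho: float = 0.8
    n_exposure: int = 26_333
    n_outcome: int = 85_844
    theta: float = 0.0
    n_instruments: int = 30
    gamma_mean: float = 0.0
    gamma_sd: float = 0.08
    prop_invalid: float = 0.0
    alpha_mean: float = 0.0
    alpha_sd: float = 0.0
    reverse_theta: float = 0.0
    p_palindromic: float = 0.05
    p_allele_swap: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if self.m_variants < 1:
            problems.append("m_variants must be >= 1")
        if not 1 <= self.n_blocks <= self.m_variants:
            problems.append("n_blocks must lie in [1, m_variants]")
        if not 0 <= self.ld_rho < 1:
            problems.append("ld_rho must lie in [0, 1)")
        if self.n_exposure <= 1 or self.n_outcome <= 1:
            problems.append("sample sizes must exceed 1")
        if not 0 <= self.n_instruments <= self.m_variants:
            problems.append("n_instruments must lie in [0, m_variants]")
        if self.n_instruments > self.n_blocks:
            problems.append(
                "n_instruments must not exceed n_blocks "
                "(each instrument heads its own LD block)"
            )
        if not 0 <= self.prop_invalid <= 1:
            problems.append("prop_invalid must lie in [0, 1]")
        if self.gamma_sd < 0 or self.alpha_sd < 0:
            problems.append("gamma_sd and alpha_sd must be >= 0")
        if not 0 <= self.p_palindromic <= 1 or not 0 <= self.p_allele_swap <= 1:
            problems.append("perturbation probabilities must lie in [0, 1]")
        if problems:
            raise ValueError("invalid SimulationConfig: " + "; ".join(problems))


@dataclass
class TruthRecord:
    """Generator ground truth for recovery tests."""

    theta: float
    instrument_ids: list[str]
    invalid_ids: list[str]
    alpha_by_id: dict[str, float]
    reverse_theta: float = 0.0


def load_scenario(name: str, **overrides) -> SimulationConfig:
    """Load a named study-condition scenario shipped with the package
    (``calibration_null``, ``recovery_strong``, ``robustness_directional``),
    optionally overriding individual fields (e.g. ``seed``)."""
    path = resources.files("mrscreen.data").joinpath(f"{name}.yaml")
    with path.open() as fh:
        raw = yaml.safe_load(fh)
    raw.update(overrides)
    return SimulationConfig(**raw)


@lru_cache(maxsize=64)
def _ar1_chol(size: int, rho: float) -> np.ndarray:
    idx = np.arange(size)
    corr = rho ** np.abs(idx[:, None] - idx[None, :])
    return np.linalg.cholesky(corr)


def _block_sizes(m: int, n_blocks: int) -> list[int]:
    base = m // n_blocks
    sizes = [base + (1 if i < m % n_blocks else 0) for i in range(n_blocks)]
    return [s for s in sizes if s > 0]


def simulate_pair(
    cfg: SimulationConfig,
) -> tuple[SummaryStats, SummaryStats, LDMatrix, TruthRecord]:
    """Generate one exposure/outcome summary-statistics pair with LD and truth.

    Fully reproducible from ``cfg.seed``; the returned tables satisfy all
    summary-statistics invariants and the LD matrix is block-diagonal AR(1).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    sizes = _block_sizes(cfg.m_variants, cfg.n_blocks)
    m = sum(sizes)

    eaf = rng.uniform(0.05, 0.95, size=m)
    se_x = 1.0 / np.sqrt(2.0 * cfg.n_exposure * eaf * (1.0 - eaf))
    se_y = 1.0 / np.sqrt(2.0 * cfg.n_outcome * eaf * (1.0 - eaf))

    # instruments head the first n_instruments blocks
    block_start = np.cumsum([0] + sizes[:-1])
    gamma = np.zeros(m)
    alpha = np.zeros(m)
    inst_idx = block_start[: cfg.n_instruments]
    gamma[inst_idx] = rng.normal(cfg.gamma_mean, cfg.gamma_sd, size=len(inst_idx))
    n_invalid = int(round(cfg.prop_invalid * len(inst_idx)))
    invalid_idx = (
        rng.choice(inst_idx, size=n_invalid, replace=False)
        if n_invalid > 0
        else np.array([], dtype=int)
    )
    alpha[invalid_idx] = rng.normal(cfg.alpha_mean, cfg.alpha_sd, size=n_invalid)

    # block structure: signed AR(1) correlation to the index variant attenuates
    # the marginal effect of LD partners and correlates their noise
    mu_x = np.zeros(m)
    mu_y = np.zeros(m)
    z_x = np.empty(m)
    z_y = np.empty(m)
    r2 = np.zeros((m, m))
    chrom = np.empty(m, dtype=object)
    pos = np.empty(m, dtype=np.int64)
    for b, (start, size) in enumerate(zip(block_start, sizes)):
        sl = slice(start, start + size)
        offsets = np.arange(size)
        r_to_index = cfg.ld_rho**offsets
        mu_x[sl] = r_to_index * gamma[start]
        mu_y[sl] = cfg.theta * mu_x[sl] + r_to_index * alpha[start]
        if size > 1 and cfg.ld_rho > 0:
            chol = _ar1_chol(size, cfg.ld_rho)
            z_x[sl] = chol @ rng.standard_normal(size)
            z_y[sl] = chol @ rng.standard_normal(size)
            corr = cfg.ld_rho ** np.abs(offsets[:, None] - offsets[None, :])
            r2[sl, sl] = corr**2
        else:
            z_x[sl] = rng.standard_normal(size)
            z_y[sl] = rng.standard_normal(size)
            r2[sl, sl] = np.eye(size)
        chrom[sl] = str(b % 22 + 1)
        pos[sl] = 10_000_000 + (b // 22) * _BLOCK_OFFSET_BP + offsets * _WITHIN_BLOCK_BP

    beta_x = mu_x + se_x * z_x
    beta_y = mu_y + se_y * z_y
    p_x = 2.0 * sps.norm.sf(np.abs(beta_x / se_x))
    p_y = 2.0 * sps.norm.sf(np.abs(beta_y / se_y))
    np.clip(p_x, np.nextafter(0, 1), 1.0, out=p_x)
    np.clip(p_y, np.nextafter(0, 1), 1.0, out=p_y)

    ids = [f"rs{100000 + i}" for i in range(m)]

    palindromic = rng.uniform(size=m) < cfg.p_palindromic
    pair_choice = rng.integers(0, 8, size=m)
    pal_choice = rng.integers(0, 4, size=m)
    ea = np.empty(m, dtype=object)
    oa = np.empty(m, dtype=object)
    for i in range(m):
        ea[i], oa[i] = (
            _PALINDROMIC_PAIRS[pal_choice[i]]
            if palindromic[i]
            else _NONPALINDROMIC_PAIRS[pair_choice[i]]
        )

    exposure_df = pd.DataFrame(
        {
            "variant_id": ids,
            "chromosome": chrom,
            "position": pos,
            "effect_allele": ea,
            "other_allele": oa,
            "eaf": eaf,
            "beta": beta_x,
            "se": se_x,
            "pvalue": p_x,
            "n": float(cfg.n_exposure),
        }
    )[CANONICAL_COLUMNS]

    # outcome reported on a possibly swapped allele frame
    swap = rng.uniform(size=m) < cfg.p_allele_swap
    out_ea = np.where(swap, oa, ea)
    out_oa = np.where(swap, ea, oa)
    outcome_df = pd.DataFrame(
        {
            "variant_id": ids,
            "chromosome": chrom,
            "position": pos,
            "effect_allele": out_ea,
            "other_allele": out_oa,
            "eaf": np.where(swap, 1.0 - eaf, eaf),
            "beta": np.where(swap, -beta_y, beta_y),
            "se": se_y,
            "pvalue": p_y,
            "n": float(cfg.n_outcome),
        }
    )[CANONICAL_COLUMNS]

    ld = LDMatrix(variant_ids=ids, r2=r2, positions=pos.copy())
    truth = TruthRecord(
        theta=cfg.theta,
        instrument_ids=[ids[i] for i in inst_idx],
        invalid_ids=sorted(ids[i] for i in invalid_idx),
        alpha_by_id={ids[i]: float(alpha[i]) for i in invalid_idx},
        reverse_theta=cfg.reverse_theta,
    )
    exposure = SummaryStats(trait_id=f"sim_exposure_{cfg.seed}", table=exposure_df)
    outcome = SummaryStats(trait_id=f"sim_outcome_{cfg.seed}", table=outcome_df)
    return exposure, outcome, ld, truth


def simulate_reverse_pair(
    cfg: SimulationConfig,
) -> tuple[SummaryStats, SummaryStats, LDMatrix, TruthRecord]:
    """The outcome->exposure direction, reusing the same machinery with roles
    swapped and ``reverse_theta`` as the causal parameter.

    Returns (outcome-as-exposure, original-exposure-as-target, ld, truth).
    """
    rcfg = replace(
        cfg,
        theta=cfg.reverse_theta,
        n_exposure=cfg.n_outcome,
        n_outcome=cfg.n_exposure,
        seed=cfg.seed + 1_000_003,  # decorrelate from the forward draw
    )
    src, target, ld, truth = simulate_pair(rcfg)
    src.trait_id = f"sim_outcome_as_exposure_{cfg.seed}"
    target.trait_id = f"sim_reverse_target_{cfg.seed}"
    return src, target, ld, truth


@dataclass
class CohortTruth:
    """Ground truth for a simulated multi-exposure cohort."""

    theta_by_exposure: dict[str, float]
    instruments_by_exposure: dict[str, list[str]]

    def planted(self) -> dict[str, float]:
        return {k: v for k, v in self.theta_by_exposure.items() if v != 0.0}


def simulate_cohort(
    n_exposures: int = 206,
    n_risk: int = 2,
    n_protective: int = 8,
    theta_risk: float = 0.15,
    theta_protective: float = -0.15,
    k_instruments: int = 10,
    block_size: int = 2,
    ld_rho: float = 0.85,
    gamma_sd: float = 0.12,
    n_exposure: int = 26_333,
    n_outcome: int = 85_844,
    p_palindromic: float = 0.05,
    p_allele_swap: float = 0.3,
    seed: int = 0,
) -> tuple[list[SummaryStats], SummaryStats, LDMatrix, CohortTruth]:
    """A batch of exposure GWAS sharing one variant grid, one outcome GWAS,
    and one LD panel — the shape of a real screening study, where every
    connectivity trait is measured on the same genotyping panel.

    Each exposure owns ``k_instruments`` disjoint LD blocks; the head variant
    of each block carries that exposure's true effect gamma ~ N(0, gamma_sd^2)
    and its within-block partners inherit AR(1)-attenuated effects and
    correlated noise, so the significance screen plus clumping is exercised.
    The first ``n_risk`` exposures have causal effect ``theta_risk`` on the
    outcome, the next ``n_protective`` have ``theta_protective``, and the rest
    are null.  The outcome aggregates all planted effects.
    """
    if n_risk + n_protective > n_exposures:
        raise ValueError("planted exposures exceed n_exposures")
    rng = np.random.default_rng(seed)
    n_blocks = n_exposures * k_instruments
    m = n_blocks * block_size

    eaf = rng.uniform(0.05, 0.95, size=m)
    se_x = 1.0 / np.sqrt(2.0 * n_exposure * eaf * (1.0 - eaf))
    se_y = 1.0 / np.sqrt(2.0 * n_outcome * eaf * (1.0 - eaf))

    offsets = np.tile(np.arange(block_size), n_blocks)
    block_of = np.repeat(np.arange(n_blocks), block_size)
    r_to_head = ld_rho**offsets
    chrom = ((block_of % 22) + 1).astype(str)
    pos = (
        10_000_000
        + (block_of // 22).astype(np.int64) * _BLOCK_OFFSET_BP
        + offsets * _WITHIN_BLOCK_BP
    )
    ids = [f"rs{100000 + i}" for i in range(m)]

    # block-diagonal AR(1) r^2
    r2 = np.zeros((m, m))
    corr_block = ld_rho ** np.abs(
        np.arange(block_size)[:, None] - np.arange(block_size)[None, :]
    )
    for b in range(n_blocks):
        sl = slice(b * block_size, (b + 1) * block_size)
        r2[sl, sl] = corr_block**2
    ld = LDMatrix(variant_ids=ids, r2=r2, positions=pos.copy())

    chol = np.linalg.cholesky(corr_block)

    def _correlated_noise() -> np.ndarray:
        u = rng.standard_normal((n_blocks, block_size))
        return (u @ chol.T).ravel()

    thetas = np.zeros(n_exposures)
    thetas[:n_risk] = theta_risk
    thetas[n_risk : n_risk + n_protective] = theta_protective

    # per-exposure true effect profile over the grid; the outcome aggregates
    mu_y = np.zeros(m)
    gammas = rng.normal(0.0, gamma_sd, size=(n_exposures, k_instruments))
    mu_x_all = np.zeros((n_exposures, m))
    truth_instruments: dict[str, list[str]] = {}
    exposure_ids = [f"sim_exp_{e:03d}" for e in range(n_exposures)]
    for e in range(n_exposures):
        heads = (np.arange(k_instruments) + e * k_instruments) * block_size
        for j, head in enumerate(heads):
            sl = slice(head, head + block_size)
            mu_x_all[e, sl] = r_to_head[sl] * gammas[e, j]
        mu_y += thetas[e] * mu_x_all[e]
        truth_instruments[exposure_ids[e]] = [ids[h] for h in heads]

    palindromic = rng.uniform(size=m) < p_palindromic
    pair_choice = rng.integers(0, 8, size=m)
    pal_choice = rng.integers(0, 4, size=m)
    ea = np.array(
        [
            (_PALINDROMIC_PAIRS[pal_choice[i]] if palindromic[i]
             else _NONPALINDROMIC_PAIRS[pair_choice[i]])[0]
            for i in range(m)
        ],
        dtype=object,
    )
    oa = np.array(
        [
            (_PALINDROMIC_PAIRS[pal_choice[i]] if palindromic[i]
             else _NONPALINDROMIC_PAIRS[pair_choice[i]])[1]
            for i in range(m)
        ],
        dtype=object,
    )

    def _table(beta, se, n, use_swap: np.ndarray | None = None) -> pd.DataFrame:
        if use_swap is None:
            t_ea, t_oa, t_eaf, t_beta = ea, oa, eaf, beta
        else:
            t_ea = np.where(use_swap, oa, ea)
            t_oa = np.where(use_swap, ea, oa)
            t_eaf = np.where(use_swap, 1.0 - eaf, eaf)
            t_beta = np.where(use_swap, -beta, beta)
        p = 2.0 * sps.norm.sf(np.abs(t_beta / se))
        np.clip(p, np.nextafter(0, 1), 1.0, out=p)
        return pd.DataFrame(
            {
                "variant_id": ids,
                "chromosome": chrom,
                "position": pos,
                "effect_allele": t_ea,
                "other_allele": t_oa,
                "eaf": t_eaf,
                "beta": t_beta,
                "se": se,
                "pvalue": p,
                "n": float(n),
            }
        )[CANONICAL_COLUMNS]

    exposures = []
    for e in range(n_exposures):
        beta_x = mu_x_all[e] + se_x * _correlated_noise()
        exposures.append(
            SummaryStats(trait_id=exposure_ids[e], table=_table(beta_x, se_x, n_exposure))
        )
    beta_y = mu_y + se_y * _correlated_noise()
    swap = rng.uniform(size=m) < p_allele_swap
    outcome = SummaryStats(
        trait_id="sim_outcome", table=_table(beta_y, se_y, n_outcome, use_swap=swap)
    )
    truth = CohortTruth(
        theta_by_exposure=dict(zip(exposure_ids, thetas)),
        instruments_by_exposure=truth_instruments,
    )
    return exposures, outcome, ld, truth


def _child_seeds(base_seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(base_seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def recovery_experiment(
    cfg: SimulationConfig,
    n_reps: int,
    methods: Sequence[str] = ("ivw", "egger", "simple_mode", "weighted_median", "weighted_mode"),
    n_boot: int = 0,
    base_seed: int | None = None,
    use_truth_instruments: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Repeated-simulation estimator evaluation against the generator truth.

    Per replicate the pair is simulated, harmonized on the true instruments
    (or on a p-value screen of the exposure when ``use_truth_instruments`` is
    False) and the requested estimators run.  Returns ``(summary, details)``:
    ``details`` has one row per replicate and method (beta, se, p, CI coverage
    of the true theta, rejection at alpha = 0.05, plus per-replicate IVW/Egger
    Q p-values and the Egger intercept test), and ``summary`` aggregates
    per-method bias, RMSE, empirical SE, mean model SE, coverage, and
    rejection rate.  ``n_boot = 0`` skips bootstrap SEs for the median/mode
    methods, leaving their coverage undefined (NaN).
    """
    from .estimators import ivw as _ivw  # local import to avoid cycles at import time
    from .estimators import mode_estimate, mr_egger, weighted_median
    from .instruments import select_by_pvalue
    from .sensitivity import cochran_q, egger_intercept_test

    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    seeds = _child_seeds(cfg.seed if base_seed is None else base_seed, 2 * n_reps)
    rows = []
    for rep in range(n_reps):
        rcfg = replace(cfg, seed=seeds[rep])
        exposure, outcome, ld, truth = simulate_pair(rcfg)
        if use_truth_instruments:
            inst = truth.instrument_ids
        else:
            inst = select_by_pvalue(exposure, 5e-6)
        h = harmonize(exposure, outcome, inst)
        if h.n_snp < 3:
            continue
        boot_seed = seeds[n_reps + rep]
        q_ivw = cochran_q(h, "ivw")
        q_egger = cochran_q(h, "egger")
        pleio = egger_intercept_test(h)
        for method in methods:
            if method == "ivw":
                est = _ivw(h)
            elif method == "egger":
                est = mr_egger(h)
            elif method == "weighted_median":
                est = weighted_median(h, n_boot=n_boot, seed=boot_seed)
            elif method == "simple_mode":
                est = mode_estimate(h, weighted=False, n_boot=n_boot, seed=boot_seed)
            elif method == "weighted_mode":
                est = mode_estimate(h, weighted=True, n_boot=n_boot, seed=boot_seed)
            else:
                raise ValueError(f"unknown method {method!r}")
            covered = (
                bool(est.ci_low <= truth.theta <= est.ci_high)
                if np.isfinite(est.se)
                else np.nan
            )
            rows.append(
                {
                    "rep": rep,
                    "method": method,
                    "beta": est.beta,
                    "se": est.se,
                    "pvalue": est.pvalue,
                    "covered": covered,
                    "reject": est.pvalue < 0.05 if np.isfinite(est.pvalue) else np.nan,
                    "n_snp": est.n_snp,
                    "q_ivw_p": q_ivw.pvalue,
                    "q_egger_p": q_egger.pvalue,
                    "egger_intercept": pleio.intercept,
                    "egger_intercept_p": pleio.pvalue,
                }
            )
    details = pd.DataFrame(rows)
    grouped = details.groupby("method", sort=False)
    summary = pd.DataFrame(
        {
            "n_reps": grouped.size(),
            "mean_beta": grouped["beta"].mean(),
            "bias": grouped["beta"].mean() - cfg.theta,
            "rmse": grouped["beta"].apply(
                lambda b: float(np.sqrt(np.mean((b - cfg.theta) ** 2)))
            ),
            "empirical_se": grouped["beta"].std(),
            "mean_se": grouped["se"].mean(),
            "coverage": grouped["covered"].mean(),
            "rejection_rate": grouped["reject"].mean(),
        }
    ).reset_index()
    return summary, details
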