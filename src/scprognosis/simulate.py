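"""Synthetic single-cell EMT and bulk survival data with known ground truth.

The single-cell generator emulates the structure of a TGF-beta-induced EMT
time course: a latent linear E -> M trajectory (uniform true pseudotime),
switch-like genes following the sigmoid profile
``f(t) = 2*mu0/(1 + exp(-k(t - t0)))`` plus Gaussian noise, hub regulators
(smooth signals whose targets are lag-shifted noisy copies along the
pseudotime ordering), stationary noise genes, and value-dependent dropout
(zeroing probability ``min(1, c*exp(-lambda*v^2))``, weighted toward low
values, calibrated so the expected zero fraction matches ``dropout_rate``).
An increasing mesenchymal marker ("VIM") and a decreasing epithelial marker
("CDH1") are always included among the switch genes.

The bulk generator draws log-normal expression and exponential survival
times with hazard ``exp(sum effect_g * z_g)`` over standardized planted
signature genes, with uniform censoring calibrated to a target rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io_formats import ClinicalTable, ExpressionMatrix, ValidationError
from .survival import SurvivalDataset


@dataclass
class ScSimConfig:
    """Single-cell simulation sizes and noise levels.

    Defaults are the desk-scale EMT study conditions used throughout the
    test-bed: 500 genes x 600 cells, 20 switch genes, 5 hubs with 8 targets
    each, 30% dropout, residual noise sd = 0.1 x the gene's mu0 scale.
    """

    G: int = 500
    C: int = 600
    n_switch: int = 20
    n_hub: int = 5
    m: int = 8
    n_flat: int | None = None  # None: fill the remaining genes
    dropout_rate: float = 0.3
    noise_sigma: float = 0.1
    dropout_lambda: float = 1.0
    seed: int = 1

    def __post_init__(self) -> None:
        structured = self.n_switch + self.n_hub * (self.m + 1)
        if self.n_flat is None:
            self.n_flat = self.G - structured
        if self.n_switch < 2:
            raise ValidationError("need n_switch >= 2 (the two EMT markers are switch genes)")
        if structured + self.n_flat > self.G or self.n_flat < 0:
            raise ValidationError(
                f"n_switch + n_hub*(m+1) + n_flat = {structured + self.n_flat} exceeds G = {self.G}")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValidationError("dropout_rate must be in [0, 1)")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be >= 0")


@dataclass
class ScSimTruth:
    """Ground truth recorded by the single-cell generator."""

    pseudotime: np.ndarray
    switch_params: pd.DataFrame          # gene, mu0, k, t0
    hub_edges: pd.DataFrame              # source, target, lag (true-order index units)
    signature: list[str]                 # switch genes + hub regulators
    expected_zero_fraction: float = 0.0
    clean_values: np.ndarray | None = None  # noiseless signal matrix (G, C)


def _sigmoid(t, mu0, k, t0):
    return 2.0 * mu0 / (1.0 + np.exp(-k * (t - t0)))


def simulate_emt_scrnaseq(cfg: ScSimConfig | None = None):
    """Generate ``(raw ExpressionMatrix, ScSimTruth)`` for one EMT course."""
    cfg = cfg or ScSimConfig()
    rng = np.random.default_rng(cfg.seed)
    t = rng.uniform(0.0, 1.0, cfg.C)
    order = np.argsort(t)

    genes, rows, signal_rows = [], [], []
    sw_records = []

    def add_switch(name, mu0, k, t0):
        clean = _sigmoid(t, mu0, k, t0)
        noisy = clean + rng.normal(0.0, cfg.noise_sigma * mu0, cfg.C)
        genes.append(name)
        rows.append(np.clip(noisy, 0.0, None))
        signal_rows.append(clean)
        sw_records.append({"gene": name, "mu0": mu0, "k": k, "t0": t0})

    # the two EMT markers are the first two switch genes
    add_switch("VIM", rng.uniform(3.0, 6.0), rng.uniform(8.0, 15.0), 0.5)
    add_switch("CDH1", rng.uniform(3.0, 6.0), -rng.uniform(8.0, 15.0), 0.5)
    for i in range(cfg.n_switch - 2):
        sign = 1.0 if rng.random() < 0.5 else -1.0
        add_switch(f"SW{i + 1:04d}", rng.uniform(3.0, 6.0),
                   sign * rng.uniform(8.0, 15.0), rng.uniform(0.25, 0.75))

    hub_edges = []
    max_lag = cfg.C // 3
    for h in range(cfg.n_hub):
        # smooth hub signal: band-limited waves with a few cycles across the
        # course. The autocorrelation must decay within a few dozen cells for
        # the regulator->target lag to be identifiable, and a multi-cycle
        # wave is non-monotone, so hubs and their lagged targets stay
        # clearly distinct from the switch-like class
        freqs = rng.uniform(3.0, 5.0, 3)
        amps = rng.uniform(0.6, 1.2, 3)
        phases = rng.uniform(0.0, 2.0 * np.pi, 3)
        base = rng.uniform(6.0, 8.0)  # hub regulators are abundant: their
        # dynamic range stays above the value-weighted dropout zone
        signal = base + sum(a * np.sin(2.0 * np.pi * f * t + p)
                            for a, f, p in zip(amps, freqs, phases))
        hub_name = f"HUB{h + 1:02d}"
        genes.append(hub_name)
        rows.append(np.clip(signal + rng.normal(0.0, cfg.noise_sigma * base, cfg.C),
                            0.0, None))
        signal_rows.append(signal)
        hub_ordered = signal[order]
        for j in range(cfg.m):
            lag = int(rng.integers(10, max(11, max_lag + 1)))
            shifted = np.empty(cfg.C)
            shifted[:lag] = hub_ordered[0]
            shifted[lag:] = hub_ordered[: cfg.C - lag]
            target = np.empty(cfg.C)
            target[order] = shifted  # back to the cells' storage order
            tname = f"TG{h + 1:02d}_{j + 1:02d}"
            genes.append(tname)
            rows.append(np.clip(target + rng.normal(0.0, cfg.noise_sigma * base, cfg.C),
                                0.0, None))
            signal_rows.append(target)
            hub_edges.append({"source": hub_name, "target": tname, "lag": lag})

    # non-dynamic genes are mostly lowly expressed, so value-weighted
    # dropout concentrates on them and on pre-activation sigmoid tails
    for i in range(cfg.n_flat):
        base = rng.uniform(0.5, 3.0)
        genes.append(f"FL{i + 1:04d}")
        rows.append(np.clip(base + rng.normal(0.0, cfg.noise_sigma * base, cfg.C),
                            0.0, None))
        signal_rows.append(np.full(cfg.C, base))

    values = np.vstack(rows)
    clean = np.vstack(signal_rows)
    expected_zero = float((values == 0).mean())
    if cfg.dropout_rate > 0:
        keep_prob = np.exp(-cfg.dropout_lambda * values ** 2)

        def excess(c):
            return float(np.minimum(1.0, c * keep_prob).mean()) - cfg.dropout_rate

        hi = 1.0
        while excess(hi) < 0 and hi < 1e12:
            hi *= 10.0
        c = hi if excess(hi) < 0 else brentq(excess, 0.0, hi)
        p_drop = np.minimum(1.0, c * keep_prob)
        already_zero = values == 0
        expected_zero = float((p_drop + (1.0 - p_drop) * already_zero).mean())
        values = np.where(rng.random(values.shape) < p_drop, 0.0, values)

    truth = ScSimTruth(
        pseudotime=t,
        switch_params=pd.DataFrame(sw_records).set_index("gene"),
        hub_edges=pd.DataFrame(hub_edges),
        signature=[r["gene"] for r in sw_records] + [f"HUB{h + 1:02d}" for h in range(cfg.n_hub)],
        expected_zero_fraction=expected_zero,
        clean_values=clean,
    )
    cells = np.asarray([f"cell{i + 1:04d}" for i in range(cfg.C)])
    return ExpressionMatrix(values, np.asarray(genes), cells), truth


def simulate_bulk_survival(signature, n_samples: int = 500, effect=None,
                           censor_rate: float = 0.3, seed: int = 0,
                           genes=None) -> SurvivalDataset:
    """Bulk cohort whose survival depends only on the planted signature.

    ``genes`` is the full gene panel of the cohort (defaults to the
    signature); non-signature genes are independent of survival. ``effect``
    gives per-signature-gene log-hazard coefficients on the standardized
    expression scale (default: +/-0.5, alternating sign).
    """
    if not 0.0 <= censor_rate < 1.0:
        raise ValidationError("censor_rate must be in [0, 1)")
    signature = list(signature)
    genes = list(genes) if genes is not None else list(signature)
    missing = [g for g in signature if g not in genes]
    if missing:
        raise ValidationError(f"signature genes not in the panel: {missing[:5]}")
    if effect is None:
        effect = np.asarray([0.5 * (-1.0) ** i for i in range(len(signature))])
    effect = np.asarray(effect, dtype=float)
    if len(effect) != len(signature):
        raise ValidationError("one effect per signature gene required")

    rng = np.random.default_rng(seed)
    mu = rng.uniform(0.5, 1.5, len(genes))
    values = np.exp(rng.normal(mu[:, None], 0.5, (len(genes), n_samples)))

    idx = [genes.index(g) for g in signature]
    sig_x = values[idx]
    z = (sig_x - sig_x.mean(axis=1, keepdims=True)) / sig_x.std(axis=1, keepdims=True)
    lp = effect @ z
    rate = 0.05 * np.exp(lp)  # baseline median survival ~ 14 time units
    times = rng.exponential(1.0 / rate)

    if censor_rate > 0:
        def expected_censoring(tau):
            # P(C < T) with C ~ U(0, tau), T ~ Exp(rate): (1 - exp(-r*tau))/(r*tau)
            x = rate * tau
            return float(np.mean((1.0 - np.exp(-x)) / x)) - censor_rate

        tau = brentq(expected_censoring, 1e-9, 1e9)
        cens = rng.uniform(0.0, tau, n_samples)
        event = (times <= cens).astype(int)
        obs = np.minimum(times, cens)
    else:
        event = np.ones(n_samples, dtype=int)
        obs = times
    obs = np.maximum(obs, 1e-9)

    samples = np.asarray([f"sample{i + 1:04d}" for i in range(n_samples)])
    expr = ExpressionMatrix(values, np.asarray(genes), samples)
    clin = ClinicalTable(samples, obs, event)
    return SurvivalDataset(expr, clin)
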