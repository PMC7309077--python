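"""Composite MRF + TV reconstruction model.

The estimator solves

    min_x  0.5 ||y - M x||^2  +  psi_MRF(W x)  +  tau2 ||x||_TV

by proximal splitting: a gradient step on the data term, MAP estimation of
the wavelet-support field, the support-conditioned soft-thresholding prox and
the TV prox applied in parallel, averaging of the two prox outputs, and an
optional Nesterov momentum extrapolation.  The accelerated solver is FCLaTV;
dropping the momentum step (and extrapolating from the current iterate) gives
CLaTV.

The API follows the model/results convention: build a
:class:`CompositeMRFTVModel` from a :class:`~mrftv.operators.KSpaceData`
container, call :meth:`~CompositeMRFTVModel.fit`, inspect the returned
:class:`ReconResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import metrics as _metrics
from . import mrf as _mrf
from .operators import KSpaceData, wavelet_analysis, wavelet_synthesis
from .prox import ProxConfig, average_prox_outputs, prox_mrf, prox_tv, tv_norm

__all__ = ["ReconConfig", "ReconState", "ReconResults",
           "CompositeMRFTVModel", "reconstruct", "reconstruct_multicoil"]

_MODES = ("magnitude", "complex", "multicoil")


@dataclass
class ReconConfig:
    """Solver configuration.

    ``accelerate`` switches between FCLaTV (True) and CLaTV (False);
    ``mode`` selects how the iterate is regularized: ``magnitude`` keeps a
    real iterate, ``complex`` and ``multicoil`` regularize real and imaginary
    parts separately with independent support fields.
    """

    max_iters: int = 100
    prox: ProxConfig = field(default_factory=ProxConfig)
    mrf_sweeps: int = 3
    k_sigma: float = 3.0
    accelerate: bool = True
    mode: str = "magnitude"
    tolerance: float = 1e-5
    seed: int = 0
    wavelet: str = "db4"
    scales: int = 3
    metric_every: int = 1
    max_mr: float = 255.0

    def __post_init__(self):
        if self.max_iters < 1:
            raise ValueError("max_iters must be >= 1")
        if self.tolerance < 0:
            raise ValueError("tolerance must be >= 0")
        if self.mrf_sweeps < 1:
            raise ValueError("mrf_sweeps must be >= 1")
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}")


@dataclass
class ReconState:
    """Iterate state and per-iteration history of one solver run."""

    x_current: np.ndarray
    x_previous: np.ndarray
    r_momentum: np.ndarray
    t_scalar: float
    iteration: int
    history: list
    converged: bool = False

    @property
    def image(self) -> np.ndarray:
        return self.x_current


class _Channel:
    """Per-channel (real or imaginary part) regularization state."""

    def __init__(self):
        self.support = None  # dict[(scale, orient)] -> SupportField (warm start)
        self.last_params = {}

    def regularize(self, ch, config: ReconConfig, rng):
        """Steps 3-5 of the solver on one real-valued channel: wavelet
        analysis, parameter estimation, MAP support, prox, synthesis."""
        theta = wavelet_analysis(ch, config.wavelet, config.scales)
        B = _mrf.estimate_threshold(theta, config.k_sigma)
        if self.support is None:
            self.support = _mrf.init_support(theta, B)
        for s, o, band in theta.detail_subbands():
            b = _mrf.estimate_scale(band, B)
            lap = _mrf.LaplacianParams(threshold_B=B, scale_b=b)
            s_init = self.support[(s, o)]
            params = _mrf.estimate_mrf_params(band, s_init)
            s_hat, _ = _mrf.map_support(band, lap, params, s_init,
                                        n_sweeps=config.mrf_sweeps, seed=rng)
            self.support[(s, o)] = s_hat
            self.last_params[(s, o)] = (lap, params)
            # shrinkage amount mu*tau1/b: the Laplacian penalty rate is 1/b
            theta.details[s - 1][o] = prox_mrf(
                band, s_hat, B, lap.rate,
                mu=config.prox.mu * config.prox.tau1)
        x1 = wavelet_synthesis(theta)
        x2 = prox_tv(ch, config.prox.mu * config.prox.tau2,
                     config.prox.tv_inner_iters)
        return average_prox_outputs(x1, x2)


class CompositeMRFTVModel:
    """MRI reconstruction with the composite MRF + TV prior.

    Parameters
    ----------
    data : KSpaceData
        Undersampled measurements, mask, and optional coil maps.
    config : ReconConfig, optional
        Solver settings; keyword overrides are applied on top.

    Examples
    --------
    >>> model = CompositeMRFTVModel(data, mode="magnitude", max_iters=50)
    >>> res = model.fit(reference=truth, seed=1)
    >>> res.summary()           # doctest: +SKIP
    """

    def __init__(self, data: KSpaceData, config: ReconConfig | None = None,
                 **overrides):
        self.data = data
        cfg = config if config is not None else ReconConfig()
        prox_keys = {"mu", "tau1", "tau2", "tv_inner_iters"}
        prox_over = {k: overrides.pop(k) for k in list(overrides)
                     if k in prox_keys}
        if prox_over:
            cfg = replace(cfg, prox=replace(cfg.prox, **prox_over))
        if overrides:
            cfg = replace(cfg, **overrides)
        if data.sensitivities is not None and cfg.mode == "magnitude":
            pass  # multi-coil data with a real-valued iterate is allowed
        self.config = cfg

    @classmethod
    def from_arrays(cls, kspace, mask, sensitivities=None, **kwargs):
        data = KSpaceData(y=kspace, mask=mask, sensitivities=sensitivities)
        return cls(data, **kwargs)

    # -- solver ------------------------------------------------------------

    def fit(self, reference=None, seed: int | None = None,
            **overrides) -> "ReconResults":
        """Run the iterative reconstruction and return the results object.

        ``reference`` (ground-truth magnitude image) enables per-iteration
        PSNR/SSIM/RLNE logging.  ``seed`` overrides the configured seed for
        the Metropolis sampler.
        """
        cfg = self.config
        if overrides:
            prox_keys = {"mu", "tau1", "tau2", "tv_inner_iters"}
            prox_over = {k: overrides.pop(k) for k in list(overrides)
                         if k in prox_keys}
            if prox_over:
                cfg = replace(cfg, prox=replace(cfg.prox, **prox_over))
            cfg = replace(cfg, **overrides)
        if seed is None:
            seed = cfg.seed
        rng = np.random.default_rng(seed)
        data = self.data
        y = data.y
        mu = cfg.prox.mu

        def grad_step(r):
            return r - mu * data.adjoint(data.forward(r) - y)

        x0 = data.adjoint(y)
        real_iterate = cfg.mode == "magnitude"
        x = x0.real.copy() if real_iterate else x0.copy()
        x_prev = x.copy()
        r = x.copy()
        t = 1.0
        channels = [_Channel()] if real_iterate else [_Channel(), _Channel()]
        history = []
        converged = False
        n_iter = 0
        for k in range(1, cfg.max_iters + 1):
            xg = grad_step(r)
            if real_iterate:
                xg = xg.real
                x_new = channels[0].regularize(xg, cfg, rng)
            else:
                re = channels[0].regularize(xg.real, cfg, rng)
                im = channels[1].regularize(xg.imag, cfg, rng)
                x_new = re + 1j * im
            if not np.all(np.isfinite(x_new)):
                raise FloatingPointError(
                    f"non-finite iterate at iteration {k}")
            rec = self._record(k, x_new, y, data, reference, cfg, channels)
            history.append(rec)
            t_next = (1.0 + np.sqrt(1.0 + 4.0 * t * t)) / 2.0
            if cfg.accelerate:
                r = x_new + ((t - 1.0) / t_next) * (x_new - x)
            else:
                r = x_new.copy()
            t = t_next
            x_prev = x
            x = x_new
            n_iter = k
            denom = float(np.linalg.norm(x_prev))
            rel = (float(np.linalg.norm(x - x_prev)) / denom
                   if denom > 0 else np.inf)
            history[-1]["rel_change"] = rel
            if rel < cfg.tolerance:
                converged = True
                break
        state = ReconState(x_current=x, x_previous=x_prev, r_momentum=r,
                           t_scalar=t, iteration=n_iter, history=history,
                           converged=converged)
        return ReconResults(self, cfg, state, reference)

    def _record(self, k, x, y, data, reference, cfg, channels):
        resid = data.forward(x) - y
        rec = {"iteration": k,
               "data_resid": float(np.linalg.norm(resid)),
               "objective_surrogate": 0.5 * float(np.linalg.norm(resid)) ** 2
               + cfg.prox.tau2 * tv_norm(np.abs(x))}
        finest = (1, "HH")
        if channels[0].last_params.get(finest) is not None:
            lap, params = channels[0].last_params[finest]
            rec.update(threshold_B=lap.threshold_B, scale_b=lap.scale_b,
                       alpha=params.alpha, beta_h=params.beta_h,
                       beta_v=params.beta_v, beta_d1=params.beta_d1,
                       beta_d2=params.beta_d2)
        if reference is not None and (k % cfg.metric_every == 0):
            rec.update(psnr=_metrics.psnr(x, reference, cfg.max_mr),
                       ssim=_metrics.ssim(x, reference, cfg.max_mr),
                       rlne=_metrics.rlne(x, reference))
        return rec


class ReconResults:
    """Reconstruction results: final image, history, diagnostics."""

    def __init__(self, model, config, state: ReconState, reference=None):
        self.model = model
        self.config = config
        self.state = state
        self.reference = reference

    @property
    def image(self) -> np.ndarray:
        """Final iterate (real in magnitude mode, complex otherwise)."""
        return self.state.x_current

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.state.x_current)

    @property
    def n_iterations(self) -> int:
        return self.state.iteration

    @property
    def converged(self) -> bool:
        return self.state.converged

    @property
    def history(self) -> pd.DataFrame:
        return pd.DataFrame(self.state.history)

    def metric_report(self, reference=None, max_mr=None):
        ref = reference if reference is not None else self.reference
        if ref is None:
            raise ValueError("no reference image available")
        return _metrics.evaluate(self.magnitude, ref,
                                 max_mr or self.config.max_mr)

    def summary(self) -> str:
        cfg = self.config
        algo = "FCLaTV" if cfg.accelerate else "CLaTV"
        lines = [
            "Composite MRF + TV reconstruction",
            "=" * 48,
            f"algorithm:        {algo} ({cfg.mode} mode)",
            f"image shape:      {self.model.data.shape}",
            f"coils:            {self.model.data.n_coils}",
            f"sampling rate:    {self.model.data.mask.rate:.4f} "
            f"({self.model.data.mask.kind})",
            f"wavelet:          {cfg.wavelet}, {cfg.scales} stationary scales",
            f"mu/tau1/tau2:     {cfg.prox.mu}/{cfg.prox.tau1}/{cfg.prox.tau2}",
            f"iterations:       {self.n_iterations}"
            f" (converged: {self.converged})",
            f"final data resid: {self.state.history[-1]['data_resid']:.4e}",
        ]
        last = self.state.history[-1]
        if "psnr" in last:
            lines += [
                f"final PSNR:       {last['psnr']:.2f} dB",
                f"final SSIM:       {last['ssim']:.4f}",
                f"final RLNE:       {last['rlne']:.4f}",
            ]
        if "beta_h" in last:
            lines += [
                "finest-subband MRF parameters (HH1):",
                f"  alpha = {last['alpha']:.4f}, "
                f"beta(h,v,d1,d2) = ({last['beta_h']:.3f}, "
                f"{last['beta_v']:.3f}, {last['beta_d1']:.3f}, "
                f"{last['beta_d2']:.3f})",
            ]
        return "\n".join(lines)


# --------------------------------------------------------------------------
# functional wrappers


def reconstruct(data: KSpaceData, config: ReconConfig | None = None,
                reference=None) -> ReconState:
    """Run the solver and return the raw :class:`ReconState`."""
    res = CompositeMRFTVModel(data, config=config).fit(reference=reference)
    return res.state


def reconstruct_multicoil(data: KSpaceData, config: ReconConfig | None = None,
                          reference=None) -> ReconState:
    """Multi-coil reconstruction; requires coil sensitivity maps."""
    if data.sensitivities is None:
        raise ValueError("multi-coil reconstruction requires sensitivities")
    return reconstruct(data, config, reference)
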