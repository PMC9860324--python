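"""Channel-sparse Bayesian lagged linear regression of EMG on neural inputs.

The decoder expresses the EMG envelope of muscle j at bin t as

    y_j(t) = sum_k sum_l w_{j,k,l} x_k(t + l*delta),   l = -10..-1, delta = 5 ms,

i.e. a linear readout of 5-50 ms of input history.  Weights are
estimated by automatic relevance determination (ARD) with *grouped*
sparsity: one relevance precision alpha_k per input channel, shared by
its 10 lag weights, so whole channels are pruned when uninformative.

The estimation is iterative evidence maximisation (MacKay updates of
the weight posterior and per-group precisions) and is deterministic:
no random initialisation, fixed update order.

Organisation follows the statsmodels convention: build a
:class:`SparseLagRegression` model from trial tensors, call ``fit()``,
and work with the returned :class:`SparseLagResults`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import linalg

from .tensors import BIN_MS, TrialTensor


@dataclass(frozen=True)
class LagSpec:
    """Lag embedding: input samples at t + l*delta feed the output at t."""

    delta_ms: float = 5.0
    l_min: int = -10
    l_max: int = -1

    def __post_init__(self) -> None:
        if self.delta_ms <= 0:
            raise ValueError("delta_ms must be positive")
        if not (self.l_min <= self.l_max < 0):
            raise ValueError("lag indices must be strictly negative with l_min <= l_max")

    @property
    def lags(self) -> np.ndarray:
        return np.arange(self.l_min, self.l_max + 1)

    @property
    def n_lags(self) -> int:
        return self.l_max - self.l_min + 1


def build_design(inputs: TrialTensor, spec: LagSpec = LagSpec()) -> tuple[np.ndarray, np.ndarray]:
    """Lag-embedded design matrix from an epoched input tensor.

    Rows are (trial, target bin) pairs, trial-major, restricted to
    target bins whose full lag history lies inside the trial window
    (the first valid target bin is ``l_min`` bins after trial start,
    i.e. -450 ms for a -500 ms epoch at defaults).  Columns are ordered
    channel-major, lag-minor (ascending lag, so the last lag column of
    a channel is l = -1).  Rows never mix samples across trials.

    Returns
    -------
    X : ndarray, shape (n_trials * n_targets, n_channels * n_lags)
    target_bins : ndarray
        Bin indices (into the tensor time axis) of each target within a
        trial, shared by all trials.
    """
    if abs(spec.delta_ms - BIN_MS) > 1e-9:
        raise ValueError("lag bin width must equal the 5-ms modulation bin")
    x = inputs.values  # (channels, trials, bins)
    n_ch, n_trials, n_bins = x.shape
    first = -spec.l_min
    if n_bins <= first:
        raise ValueError(f"trial too short: need more than {first} bins")
    target_bins = np.arange(first, n_bins)
    n_t = target_bins.size
    X = np.empty((n_trials * n_t, n_ch * spec.n_lags))
    for j, l in enumerate(spec.lags):
        # column block j of every channel: x[:, :, targets + l]
        seg = x[:, :, target_bins + l]                     # (ch, trials, n_t)
        # column k * n_lags + j <- channel k at lag index j (channel-major)
        X[:, j :: spec.n_lags] = seg.transpose(1, 2, 0).reshape(n_trials * n_t, n_ch)
    return X, target_bins


def build_targets(emg: TrialTensor, target_bins: np.ndarray) -> np.ndarray:
    """Target matrix aligned with :func:`build_design` rows: (rows, muscles)."""
    y = emg.values[:, :, target_bins]                      # (muscles, trials, n_t)
    return y.transpose(1, 2, 0).reshape(-1, emg.n_entities)


# ---------------------------------------------------------------------------
# grouped ARD core
# ---------------------------------------------------------------------------

@dataclass
class ARDFit:
    weights: np.ndarray       # (p,) with pruned groups exactly zero
    alpha: np.ndarray         # (n_groups,) relevance precision, inf if pruned
    beta: float               # noise precision
    pruned: np.ndarray        # (n_groups,) bool
    n_iter: int
    converged: bool
    evidence: float


def ard_group_fit(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> ARDFit:
    """Evidence-maximisation ARD with one precision per column group.

    Deterministic given the data: the noise precision starts at
    1/(0.1 var(y)) and group precisions start weakly informative, so the
    first posterior mean is close to ridge/OLS before sparsification.
    Groups are pruned (weights set exactly to zero) once their effective
    degrees of freedom vanish.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in design or targets")
    n, p = X.shape
    if n < p / 5:
        warnings.warn("fewer rows than columns/5: fit may be unstable", stacklevel=2)
    return _ard_from_moments(
        X.T @ X, X.T @ y, float(y @ y), float(y.mean()), n, groups,
        max_iter=max_iter, tol=tol,
    )


def _ard_from_moments(
    G: np.ndarray,
    Xty: np.ndarray,
    yty: float,
    y_mean: float,
    n: int,
    groups: np.ndarray,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> ARDFit:
    """ARD from sufficient statistics (shared Gram matrix across targets)."""
    p = G.shape[0]
    groups = np.asarray(groups, dtype=int)
    n_groups = int(groups.max()) + 1
    var_y = yty / n - y_mean**2
    if var_y <= 0 or yty == 0.0:
        # degenerate target: everything pruned
        return ARDFit(
            weights=np.zeros(p),
            alpha=np.full(n_groups, np.inf),
            beta=np.inf,
            pruned=np.ones(n_groups, dtype=bool),
            n_iter=0,
            converged=True,
            evidence=0.0,
        )

    diag_scale = float(np.mean(np.diag(G)))
    beta = 1.0 / (0.1 * var_y)
    beta_max = 1e12 / var_y
    alpha = np.full(n_groups, 1e-6 * beta * diag_scale)
    active = np.ones(n_groups, dtype=bool)
    group_cols = [np.nonzero(groups == g)[0] for g in range(n_groups)]
    d_k = np.array([c.size for c in group_cols])

    weights = np.zeros(p)
    evidence = -np.inf
    converged = False
    total_iter = 0

    def posterior(active_ids: np.ndarray) -> dict:
        """Posterior moments and log evidence at the current (alpha, beta)."""
        cols = np.concatenate([group_cols[g] for g in active_ids])
        a_cols = np.repeat(alpha[active_ids], d_k[active_ids])
        G_aa = G[np.ix_(cols, cols)]
        S = beta * G_aa + np.diag(a_cols)
        cho = linalg.cho_factor(S, lower=True)
        sigma = linalg.cho_solve(cho, np.eye(cols.size))
        mu = beta * (sigma @ Xty[cols])
        r2 = max(float(yty - 2.0 * mu @ Xty[cols] + mu @ (G_aa @ mu)), 0.0)
        logdet_S = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
        ev = 0.5 * (
            float(np.sum(d_k[active_ids] * np.log(alpha[active_ids])))
            + n * np.log(beta)
            - beta * r2
            - float(np.sum(a_cols * mu**2))
            - logdet_S
            - n * np.log(2.0 * np.pi)
        )
        return {
            "cols": cols, "a_cols": a_cols, "G_aa": G_aa, "sigma": sigma,
            "mu": mu, "r2": r2, "logdet_S": logdet_S, "evidence": ev,
        }

    def evidence_without(post: dict, active_ids: np.ndarray, i: int) -> float:
        """Log evidence with group ``active_ids[i]`` removed (alpha, beta fixed).

        Uses the partitioned inverse of S, so no refactorisation:
        mu' = mu_r - Sigma_rg Sigma_gg^{-1} mu_g and
        log|S_rr| = log|S| + log|Sigma_gg|.
        """
        bounds = np.concatenate([[0], np.cumsum(d_k[active_ids])])
        sl = slice(bounds[i], bounds[i + 1])
        keep = np.ones(post["mu"].size, dtype=bool)
        keep[sl] = False
        sigma = post["sigma"]
        sgg = sigma[sl, sl]
        mu_g = post["mu"][sl]
        mu_r = post["mu"][keep] - sigma[keep, sl] @ np.linalg.solve(sgg, mu_g)
        cols_r = post["cols"][keep]
        r2 = max(
            float(yty - 2.0 * mu_r @ Xty[cols_r]
                  + mu_r @ (post["G_aa"][np.ix_(keep, keep)] @ mu_r)),
            0.0,
        )
        sign, logdet_gg = np.linalg.slogdet(sgg)
        if sign <= 0:
            return -np.inf
        logdet = post["logdet_S"] + logdet_gg
        rest = np.delete(active_ids, i)
        return 0.5 * (
            float(np.sum(d_k[rest] * np.log(alpha[rest])))
            + n * np.log(beta)
            - beta * r2
            - float(np.sum(post["a_cols"][keep] * mu_r**2))
            - logdet
            - n * np.log(2.0 * np.pi)
        )

    def set_weights(post: dict, active_ids: np.ndarray) -> None:
        weights[:] = 0.0
        offset = 0
        for g in active_ids:
            weights[group_cols[g]] = post["mu"][offset : offset + d_k[g]]
            offset += d_k[g]

    for _round in range(10):
        # ---- smooth MacKay updates to evidence convergence ------------
        evidence_prev = -np.inf
        round_converged = False
        while total_iter < max_iter:
            total_iter += 1
            active_ids = np.nonzero(active)[0]
            if active_ids.size == 0:
                break
            post = posterior(active_ids)
            evidence = post["evidence"]
            set_weights(post, active_ids)
            if np.isfinite(evidence_prev) and abs(evidence - evidence_prev) < tol * max(
                1.0, abs(evidence)
            ):
                round_converged = True
                break
            evidence_prev = evidence

            mu, sigma, r2 = post["mu"], post["sigma"], post["r2"]
            sig_diag = np.diag(sigma)
            gamma_total = 0.0
            offset = 0
            for g in active_ids:
                d = d_k[g]
                sl = slice(offset, offset + d)
                gamma = d - alpha[g] * float(sig_diag[sl].sum())
                gamma = min(max(gamma, 0.0), float(d))
                mu_norm2 = float(mu[sl] @ mu[sl])
                alpha[g] = gamma / max(mu_norm2, 1e-300)
                gamma_total += gamma
                offset += d
                # vanishing effective dof: remove from the active set
                if gamma < 1e-5 * d or not np.isfinite(alpha[g]):
                    active[g] = False
                    alpha[g] = np.inf
            beta = min((n - gamma_total) / max(r2, n * var_y * 1e-15), beta_max)

        if not active.any():
            evidence = 0.0
            weights[:] = 0.0
            converged = True
            break
        converged = round_converged

        # ---- discrete elimination: alpha -> inf is a boundary optimum
        # the smooth updates cannot reach.  A retained group must buy more
        # evidence than the Occam correction for its type-II-optimised
        # hyperparameter (0.5 ln n per group); otherwise it is dropped.
        margin = 0.5 * np.log(n)
        removed_any = False
        while active.sum() > 1:
            active_ids = np.nonzero(active)[0]
            post = posterior(active_ids)
            evidence = post["evidence"]
            set_weights(post, active_ids)
            gains = np.array([
                evidence_without(post, active_ids, i) - evidence
                for i in range(active_ids.size)
            ])
            best = int(np.argmax(gains))
            if gains[best] <= -margin:
                break
            g = active_ids[best]
            active[g] = False
            alpha[g] = np.inf
            removed_any = True
        if not removed_any:
            break

    if not converged:
        warnings.warn("ARD did not converge within max_iter", stacklevel=2)

    # final hard mask: negligible posterior weight mass -> exact zero
    norms = np.array([np.linalg.norm(weights[c]) for c in group_cols])
    max_norm = norms.max() if norms.size else 0.0
    tiny = norms < 1e-8 * max_norm if max_norm > 0 else np.ones_like(norms, dtype=bool)
    pruned = ~active | tiny
    for g in np.nonzero(pruned)[0]:
        weights[group_cols[g]] = 0.0
        alpha[g] = np.inf
    return ARDFit(
        weights=weights,
        alpha=alpha,
        beta=float(beta),
        pruned=pruned,
        n_iter=total_iter,
        converged=converged,
        evidence=float(evidence),
    )


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class SparseLagRegression:
    """Lagged EMG decoder with per-channel ARD sparsity.

    Parameters
    ----------
    emg
        Epoched EMG modulation tensor (targets), one model per muscle.
    inputs
        Epoched input tensor (descending and/or afferent channels).
    channel_classes
        Array of ``"descending"``/``"afferent"`` per input channel.
    lag_spec
        The lag embedding; defaults to 5-50 ms of history at 5 ms.
    """

    def __init__(
        self,
        emg: TrialTensor,
        inputs: TrialTensor,
        channel_classes: np.ndarray | None = None,
        lag_spec: LagSpec = LagSpec(),
    ) -> None:
        if emg.n_trials != inputs.n_trials:
            raise ValueError("EMG and inputs carry different trial counts")
        if not np.allclose(emg.times, inputs.times):
            raise ValueError("EMG and inputs must share a time axis")
        self.emg = emg
        self.inputs = inputs
        self.lag_spec = lag_spec
        self.channel_classes = (
            np.asarray(channel_classes)
            if channel_classes is not None
            else np.array(["descending"] * inputs.n_entities)
        )
        if self.channel_classes.size != inputs.n_entities:
            raise ValueError("one class label per input channel required")

    def subset(self, keep: np.ndarray) -> "SparseLagRegression":
        """Model restricted to a subset of input channels (boolean or index)."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.nonzero(keep)[0]
        return SparseLagRegression(
            self.emg,
            self.inputs.select_entities(keep),
            self.channel_classes[keep],
            self.lag_spec,
        )

    def restricted(self, variant: str) -> "SparseLagRegression":
        """``"both"``, ``"descending"`` or ``"afferent"`` input variant."""
        if variant == "both":
            return self
        if variant not in ("descending", "afferent"):
            raise ValueError(f"unknown variant {variant!r}")
        return self.subset(self.channel_classes == variant)

    def fit(self, max_iter: int = 500, tol: float = 1e-6) -> "SparseLagResults":
        X, target_bins = build_design(self.inputs, self.lag_spec)
        Y = build_targets(self.emg, target_bins)
        if not (np.isfinite(X).all() and np.isfinite(Y).all()):
            raise ValueError("non-finite values in design or targets")
        groups = np.repeat(np.arange(self.inputs.n_entities), self.lag_spec.n_lags)
        n_lags = self.lag_spec.n_lags
        n, p = X.shape
        if n < p / 5:
            warnings.warn("fewer rows than columns/5: fit may be unstable", stacklevel=2)
        G = X.T @ X
        XtY = X.T @ Y
        fits = [
            _ard_from_moments(
                G, XtY[:, j], float(Y[:, j] @ Y[:, j]), float(Y[:, j].mean()),
                n, groups, max_iter=max_iter, tol=tol,
            )
            for j in range(Y.shape[1])
        ]
        weights = np.stack([f.weights.reshape(-1, n_lags) for f in fits])
        return SparseLagResults(
            model=self,
            weights=weights,
            alpha=np.stack([f.alpha for f in fits]),
            pruned=np.stack([f.pruned for f in fits]),
            noise_precision=np.array([f.beta for f in fits]),
            n_iter=np.array([f.n_iter for f in fits]),
            converged=np.array([f.converged for f in fits]),
            evidence=np.array([f.evidence for f in fits]),
            target_bins=target_bins,
        )


@dataclass
class SparseLagResults:
    """Fitted decoder: weights, per-channel relevance, diagnostics."""

    model: SparseLagRegression
    weights: np.ndarray          # (n_muscles, n_inputs, n_lags)
    alpha: np.ndarray            # (n_muscles, n_inputs)
    pruned: np.ndarray           # (n_muscles, n_inputs) bool
    noise_precision: np.ndarray  # (n_muscles,)
    n_iter: np.ndarray
    converged: np.ndarray
    evidence: np.ndarray
    target_bins: np.ndarray
    channel_labels: list[str] = field(init=False)

    def __post_init__(self) -> None:
        self.channel_labels = list(self.model.inputs.labels)

    @property
    def muscle_names(self) -> list[str]:
        return list(self.model.emg.labels)

    @property
    def channel_classes(self) -> np.ndarray:
        return self.model.channel_classes

    # -- prediction ------------------------------------------------------
    def _check_inputs(self, inputs: TrialTensor) -> TrialTensor:
        if inputs.n_entities != len(self.channel_labels):
            raise ValueError(
                f"model expects {len(self.channel_labels)} input channels, "
                f"got {inputs.n_entities}"
            )
        if inputs.labels != self.channel_labels:
            raise ValueError("input channel labels do not match the fitted model")
        return inputs

    def channel_contribution(self, inputs: TrialTensor, channel: int) -> np.ndarray:
        """One channel's share of the reconstruction: (muscles, trials, targets)."""
        spec = self.model.lag_spec
        first = -spec.l_min
        x = inputs.values[channel]                          # (trials, bins)
        n_t = inputs.n_bins - first
        stack = np.stack(
            [x[:, first + l : first + l + n_t] for l in spec.lags], axis=0
        )                                                   # (lags, trials, targets)
        return np.tensordot(self.weights[:, channel, :], stack, axes=(1, 0))

    def predict(self, inputs: TrialTensor | None = None, channels=None) -> TrialTensor:
        """Reconstruction on the valid target bins (-450..1500 ms at defaults).

        ``channels`` restricts the summation to a channel subset (the
        linear component of those inputs); the full reconstruction is
        the sum over every channel, accumulated per channel in index
        order so components over any partition add up exactly.
        """
        inputs = self._check_inputs(inputs if inputs is not None else self.model.inputs)
        spec = self.model.lag_spec
        first = -spec.l_min
        if channels is None:
            channels = np.arange(inputs.n_entities)
        channels = np.asarray(channels)
        if channels.dtype == bool:
            channels = np.nonzero(channels)[0]
        if channels.size and (channels.min() < 0 or channels.max() >= inputs.n_entities):
            raise ValueError("channel index out of range for this model")
        n_t = inputs.n_bins - first
        out = np.zeros((self.weights.shape[0], inputs.n_trials, n_t))
        for k in np.sort(channels):
            out += self.channel_contribution(inputs, int(k))
        times = inputs.times[first:]
        return TrialTensor(
            out, times, self.muscle_names, kind="reconstruction", stage="epoched"
        )

    # -- diagnostics -----------------------------------------------------
    def retained_proportion(self, channel_class: str | None = None) -> np.ndarray:
        """Unpruned channel fraction per muscle, optionally per input class."""
        mask = (
            np.ones(self.pruned.shape[1], dtype=bool)
            if channel_class is None
            else self.channel_classes == channel_class
        )
        if not mask.any():
            raise ValueError(f"no channels of class {channel_class!r}")
        return 1.0 - self.pruned[:, mask].mean(axis=1)

    def summary(self) -> str:
        lines = [
            "Sparse lagged EMG decoder (grouped ARD)",
            f"  inputs: {len(self.channel_labels)} channels x "
            f"{self.model.lag_spec.n_lags} lags "
            f"({-self.model.lag_spec.l_max * self.model.lag_spec.delta_ms:.0f}-"
            f"{-self.model.lag_spec.l_min * self.model.lag_spec.delta_ms:.0f} ms history)",
            f"  muscles: {len(self.muscle_names)}",
            "",
            f"  {'muscle':<12}{'retained':>9}{'desc':>7}{'aff':>7}"
            f"{'iters':>7}{'conv':>6}{'noise SD':>10}",
        ]
        has_aff = (self.channel_classes == "afferent").any()
        has_desc = (self.channel_classes == "descending").any()
        for j, name in enumerate(self.muscle_names):
            kept = 1.0 - self.pruned[j].mean()
            rd = self.retained_proportion("descending")[j] if has_desc else np.nan
            ra = self.retained_proportion("afferent")[j] if has_aff else np.nan
            lines.append(
                f"  {name:<12}{kept:>9.2f}{rd:>7.2f}{ra:>7.2f}"
                f"{self.n_iter[j]:>7d}{str(bool(self.converged[j])):>6}"
                f"{1.0 / np.sqrt(self.noise_precision[j]):>10.3g}"
            )
        return "\n".join(lines)
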