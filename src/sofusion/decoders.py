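"""Omics-specific probabilistic decoders and reconstruction likelihoods.

Each decoder maps the joint representation Z through a shared hidden stack
f_D and per-parameter linear heads:

- RNA   : zero-inflated negative binomial (dropout pi, mean mu, dispersion
  theta), NLL summed over spots and genes.
- ATAC  : Bernoulli accessibility probability p, binary cross-entropy.
- ADT   : mixture of two negative binomials sharing a per-protein dispersion
  phi; the background mean nu_b has a log-normal posterior regularized
  toward a log-normal prior initialized from a two-component GMM on
  log counts, and the foreground mean is nu_f = (1 + alpha) * nu_b so the
  foreground always dominates the background.
- other : sigmoid reconstruction with elementwise cross-entropy against
  [0, 1]-scaled intensities.

All likelihoods are evaluated in log space; mixtures use log-sum-exp.
The negative binomial is in mean-dispersion form,
``NB(x | mu, theta) = Gamma(x+theta) / (Gamma(theta) x!) *
(theta/(theta+mu))^theta * (mu/(theta+mu))^x`` (variance mu + mu^2/theta).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.mixture import GaussianMixture

from . import _autodiff as ad

__all__ = [
    "ZINBParams", "BernoulliParams", "NBMixtureParams",
    "ZINBDecoder", "BernoulliDecoder", "ADTDecoder", "UniversalDecoder",
    "zinb_params", "zinb_nll", "bernoulli_params", "atac_bce",
    "fit_gmm_prior", "adt_params", "nb_mixture_nll",
    "generic_reconstruction_loss", "total_reconstruction_loss",
]

_PI_EPS = 1e-7
_EXP_LO, _EXP_HI = 1e-5, 1e6


@dataclass
class ZINBParams:
    pi: np.ndarray
    mu: np.ndarray
    theta: np.ndarray


@dataclass
class BernoulliParams:
    p: np.ndarray


@dataclass
class NBMixtureParams:
    nu_b: np.ndarray
    nu_f: np.ndarray
    pi_adt: np.ndarray
    phi: np.ndarray
    alpha_adt: np.ndarray | None = None
    m_b: np.ndarray | None = None
    sigma_b: np.ndarray | None = None
    m_prior: np.ndarray | None = None
    sigma_prior: np.ndarray | None = None


def _t(x) -> ad.Tensor:
    return x if isinstance(x, ad.Tensor) else ad.Tensor(np.asarray(x, dtype=float))


def _data(x) -> np.ndarray:
    return x.data if isinstance(x, ad.Tensor) else np.asarray(x, dtype=float)


def _check_count_matrix(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if (x < 0).any():
        raise ValueError("count matrix has negative entries")
    if not np.allclose(x, np.round(x)):
        raise ValueError("count matrix must be integer-valued")
    return x


# -- shared building blocks ----------------------------------------------------

class _Dense:
    """Affine layer with optional activation."""

    def __init__(self, rng, d_in, d_out, activation=None):
        self.W = ad.Parameter(ad.glorot(rng, d_in, d_out))
        self.b = ad.Parameter(np.zeros(d_out))
        self.activation = activation

    def __call__(self, x: ad.Tensor) -> ad.Tensor:
        h = x @ self.W + self.b
        return self.activation(h) if self.activation else h

    def parameters(self):
        return [self.W, self.b]


class _DecoderBase:
    """Shared hidden stack f_D (one ELU layer by default)."""

    def __init__(self, rng, latent_dim, hidden_dim=64):
        self.trunk = _Dense(rng, latent_dim, hidden_dim, activation=ad.elu)
        self.hidden_dim = hidden_dim

    def hidden(self, Z: ad.Tensor) -> ad.Tensor:
        return self.trunk(Z)

    def parameters(self):
        return self.trunk.parameters()


def _log_nb(x: ad.Tensor, mu: ad.Tensor, theta: ad.Tensor) -> ad.Tensor:
    """Elementwise log NB(x | mu, theta) in mean-dispersion form."""
    from scipy.special import gammaln as _gammaln

    log_tm = ad.log(theta + mu)
    # x is observed data: its factorial term is a constant of the graph
    log_fact = ad.Tensor(_gammaln(x.data + 1.0))
    return (
        ad.lgamma(x + theta) - ad.lgamma(theta) - log_fact
        + theta * (ad.log(theta) - log_tm)
        + x * (ad.log(mu) - log_tm)
    )


# -- RNA: ZINB -----------------------------------------------------------------

class ZINBDecoder(_DecoderBase):
    def __init__(self, rng, latent_dim, n_features, hidden_dim=64):
        super().__init__(rng, latent_dim, hidden_dim)
        self.head_pi = _Dense(rng, hidden_dim, n_features)
        self.head_mu = _Dense(rng, hidden_dim, n_features)
        self.head_theta = _Dense(rng, hidden_dim, n_features)

    def forward(self, Z: ad.Tensor):
        h = self.hidden(Z)
        pi = ad.clamp(ad.sigmoid(self.head_pi(h)), _PI_EPS, 1.0 - _PI_EPS)
        mu = ad.clamp(ad.exp(self.head_mu(h)), _EXP_LO, _EXP_HI)
        theta = ad.clamp(ad.exp(self.head_theta(h)), _EXP_LO, _EXP_HI)
        return pi, mu, theta

    def parameters(self):
        return (super().parameters() + self.head_pi.parameters()
                + self.head_mu.parameters() + self.head_theta.parameters())

    def loss(self, x: np.ndarray, Z: ad.Tensor) -> ad.Tensor:
        pi, mu, theta = self.forward(Z)
        return _zinb_nll_core(ad.Tensor(x), pi, mu, theta)


def zinb_params(Z, decoder: ZINBDecoder) -> ZINBParams:
    """Evaluate the ZINB parameter heads on Z (plain-array view)."""
    pi, mu, theta = decoder.forward(_t(Z))
    return ZINBParams(pi=pi.data, mu=mu.data, theta=theta.data)


def _zinb_nll_core(x, pi, mu, theta) -> ad.Tensor:
    log_nb = _log_nb(x, mu, theta)
    log_pi = ad.log(pi)
    log_1mpi = ad.log(1.0 - pi)
    zero_case = ad.logaddexp(log_pi, log_1mpi + log_nb)
    pos_case = log_1mpi + log_nb
    ll = ad.where(x.data == 0, zero_case, pos_case)
    return -ll.sum()


def zinb_nll(x, params: ZINBParams) -> float:
    """Negative log-likelihood of counts under ZINB(pi, mu, theta), summed
    over all spots and genes.  ZINB(0) = pi + (1-pi) NB(0); ZINB(x>0) =
    (1-pi) NB(x)."""
    x = _check_count_matrix(_data(x))
    out = _zinb_nll_core(_t(x), _t(params.pi), _t(params.mu), _t(params.theta))
    return float(out.data)


# -- ATAC: Bernoulli -----------------------------------------------------------

class BernoulliDecoder(_DecoderBase):
    def __init__(self, rng, latent_dim, n_features, hidden_dim=64):
        super().__init__(rng, latent_dim, hidden_dim)
        self.head_p = _Dense(rng, hidden_dim, n_features)

    def forward(self, Z: ad.Tensor) -> ad.Tensor:
        return ad.clamp(ad.sigmoid(self.head_p(self.hidden(Z))), _PI_EPS, 1.0 - _PI_EPS)

    def parameters(self):
        return super().parameters() + self.head_p.parameters()

    def loss(self, x: np.ndarray, Z: ad.Tensor) -> ad.Tensor:
        p = self.forward(Z)
        return _bce_core(ad.Tensor(x), p)


def bernoulli_params(Z, decoder: BernoulliDecoder) -> BernoulliParams:
    return BernoulliParams(p=decoder.forward(_t(Z)).data)


def _bce_core(x, p) -> ad.Tensor:
    return -(x * ad.log(p) + (1.0 - x) * ad.log(1.0 - p)).sum()


def atac_bce(x, params: BernoulliParams) -> float:
    """Total binary cross-entropy between binary accessibility and p."""
    x = _data(x)
    if not np.isin(x, (0.0, 1.0)).all():
        raise ValueError("ATAC matrix must be binary (0/1)")
    return float(_bce_core(_t(x), _t(params.p)).data)


# -- ADT: NB mixture with log-normal background --------------------------------

def fit_gmm_prior(adt_counts: np.ndarray, seed: int = 0):
    """Per-protein background prior from a 2-component GMM on log1p counts.

    Returns (m_prior, sigma_prior), each of length d: the mean and standard
    deviation of the lower-mean mixture component, used to initialize the
    log-normal prior on the background intensity nu_b.  Degenerate proteins
    (constant counts) fall back to (mean, 0.5*|mean| + 0.1).
    """
    counts = _check_count_matrix(np.asarray(adt_counts, dtype=float))
    logged = np.log1p(counts)
    d = logged.shape[1]
    m_prior = np.empty(d)
    sigma_prior = np.empty(d)
    for p in range(d):
        col = logged[:, p]
        mean = float(col.mean())
        if np.ptp(col) < 1e-12:
            m_prior[p] = mean
            sigma_prior[p] = 0.5 * abs(mean) + 0.1
            continue
        gmm = GaussianMixture(n_components=2, random_state=seed, n_init=1,
                              max_iter=200)
        gmm.fit(col[:, None])
        lo = int(np.argmin(gmm.means_.ravel()))
        m_prior[p] = float(gmm.means_.ravel()[lo])
        sigma_prior[p] = float(max(np.sqrt(gmm.covariances_.ravel()[lo]), 1e-3))
    return m_prior, sigma_prior


class ADTDecoder(_DecoderBase):
    """Heads for the background log-normal posterior (m_b, sigma_b), the
    background probability pi, and the foreground excess alpha; plus the
    trainable per-protein dispersion phi and the trainable prior."""

    def __init__(self, rng, latent_dim, n_features, prior, hidden_dim=64):
        super().__init__(rng, latent_dim, hidden_dim)
        self.head_m = _Dense(rng, hidden_dim, n_features)
        self.head_sigma = _Dense(rng, hidden_dim, n_features)
        self.head_pi = _Dense(rng, hidden_dim, n_features)
        self.head_alpha = _Dense(rng, hidden_dim, n_features)
        m0, s0 = prior
        self.m_prior = ad.Parameter(np.asarray(m0, dtype=float))
        self.log_sigma_prior = ad.Parameter(np.log(np.asarray(s0, dtype=float)))
        self.log_phi = ad.Parameter(np.zeros(n_features))
        # start the posterior mean heads at the prior so nu_b opens near the
        # GMM background estimate
        self.head_m.b.data[:] = np.asarray(m0, dtype=float)

    def parameters(self):
        return (super().parameters() + self.head_m.parameters()
                + self.head_sigma.parameters() + self.head_pi.parameters()
                + self.head_alpha.parameters()
                + [self.m_prior, self.log_sigma_prior, self.log_phi])

    def forward(self, Z: ad.Tensor, sample: bool = False,
                rng: np.random.Generator | None = None):
        h = self.hidden(Z)
        m_b = self.head_m(h)
        sigma_b = ad.clamp(ad.exp(self.head_sigma(h)), 1e-3, 1e2)
        if sample:
            if rng is None:
                raise ValueError("sampling requires an RNG")
            eps = rng.standard_normal(m_b.shape)
            nu_b = ad.exp(m_b + sigma_b * ad.Tensor(eps))
        else:
            nu_b = ad.exp(m_b + 0.5 * sigma_b * sigma_b)
        nu_b = ad.clamp(nu_b, _EXP_LO, _EXP_HI)
        pi = ad.clamp(ad.sigmoid(self.head_pi(h)), _PI_EPS, 1.0 - _PI_EPS)
        alpha = ad.softplus(self.head_alpha(h))
        nu_f = (1.0 + alpha) * nu_b
        phi = ad.clamp(ad.exp(self.log_phi), _EXP_LO, _EXP_HI)
        return nu_b, nu_f, pi, phi, alpha, m_b, sigma_b

    def loss(self, x: np.ndarray, Z: ad.Tensor, sample: bool,
             rng: np.random.Generator | None, kl_weight: float = 1.0) -> ad.Tensor:
        nu_b, nu_f, pi, phi, alpha, m_b, sigma_b = self.forward(Z, sample, rng)
        nll = _nb_mixture_nll_core(ad.Tensor(x), nu_b, nu_f, pi, phi)
        if kl_weight > 0:
            kl = _lognormal_kl(m_b, sigma_b, self.m_prior,
                               ad.exp(self.log_sigma_prior))
            nll = nll + kl_weight * kl
        return nll


def adt_params(Z, decoder: ADTDecoder, sample: bool = False,
               rng: np.random.Generator | None = None) -> NBMixtureParams:
    """Evaluate the ADT heads on Z; evaluation mode uses the analytic
    log-normal mean exp(m_b + sigma_b^2/2) for nu_b."""
    nu_b, nu_f, pi, phi, alpha, m_b, sigma_b = decoder.forward(_t(Z), sample, rng)
    return NBMixtureParams(
        nu_b=nu_b.data, nu_f=nu_f.data, pi_adt=pi.data, phi=phi.data,
        alpha_adt=alpha.data, m_b=m_b.data, sigma_b=sigma_b.data,
        m_prior=decoder.m_prior.data.copy(),
        sigma_prior=np.exp(decoder.log_sigma_prior.data),
    )


def _lognormal_kl(m_q, s_q, m_p, s_p) -> ad.Tensor:
    """KL(lognormal(m_q, s_q) || lognormal(m_p, s_p)) summed over entries;
    equals the Gaussian KL on the log scale."""
    return (
        ad.log(s_p) - ad.log(s_q)
        + (s_q * s_q + (m_q - m_p) ** 2.0) / (2.0 * s_p * s_p)
        - 0.5
    ).sum()


def _nb_mixture_nll_core(x, nu_b, nu_f, pi, phi) -> ad.Tensor:
    log_b = ad.log(pi) + _log_nb(x, nu_b, phi)
    log_f = ad.log(1.0 - pi) + _log_nb(x, nu_f, phi)
    return -ad.logaddexp(log_b, log_f).sum()


def nb_mixture_nll(x, params: NBMixtureParams, kl_weight: float = 1.0) -> float:
    """NLL of the two-component NB mixture (log-sum-exp over components),
    plus the closed-form KL between the background posterior and prior
    log-normals when both are present in ``params``."""
    x = _check_count_matrix(_data(x))
    out = _nb_mixture_nll_core(_t(x), _t(params.nu_b), _t(params.nu_f),
                               _t(params.pi_adt), _t(params.phi))
    if (kl_weight > 0 and params.m_b is not None and params.m_prior is not None):
        out = out + kl_weight * _lognormal_kl(
            _t(params.m_b), _t(params.sigma_b),
            _t(params.m_prior), _t(params.sigma_prior))
    return float(out.data)


# -- universal decoder ---------------------------------------------------------

class UniversalDecoder(_DecoderBase):
    def __init__(self, rng, latent_dim, n_features, hidden_dim=64):
        super().__init__(rng, latent_dim, hidden_dim)
        self.head = _Dense(rng, hidden_dim, n_features)

    def forward(self, Z: ad.Tensor) -> ad.Tensor:
        return ad.clamp(ad.sigmoid(self.head(self.hidden(Z))), _PI_EPS, 1.0 - _PI_EPS)

    def parameters(self):
        return super().parameters() + self.head.parameters()

    def loss(self, x: np.ndarray, Z: ad.Tensor) -> ad.Tensor:
        return _bce_core(ad.Tensor(x), self.forward(Z))


def generic_reconstruction_loss(x, Z, decoder: UniversalDecoder) -> float:
    """Elementwise cross-entropy between sigmoid reconstruction and targets
    scaled to [0, 1]."""
    x = _data(x)
    if (x < 0).any() or (x > 1).any():
        raise ValueError(
            "targets must lie in [0, 1]; run preprocess_other on the raw matrix"
        )
    return float(decoder.loss(x, _t(Z)).data)


def total_reconstruction_loss(losses) -> float | ad.Tensor:
    """Sum of the active modalities' reconstruction losses."""
    if isinstance(losses, dict):
        losses = list(losses.values())
    losses = [l for l in losses if l is not None]
    if not losses:
        raise ValueError("no active modality losses to sum")
    total = losses[0]
    for l in losses[1:]:
        total = total + l
    return total
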