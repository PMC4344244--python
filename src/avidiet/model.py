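"""Hierarchical Bayesian imputation of unidentified diet items (MOPs).

The model
---------
For one species, let ``y[m, k, l]`` be the number of identified feeding
episodes in month ``m`` with diet item ``k`` caught at location ``l``, and
``u[m, l]`` the number of episodes at location ``l`` whose item could not be
identified.  The model assumes:

* Each episode's item is drawn from the month's item distribution
  ``pi[m] ∝ lambda[m, :]``, where ``lambda[m, k]`` is the expected foraging
  frequency of item ``k`` in month ``m``.  Counts are parameterised as
  ``n[m, k] ~ Poisson(lambda[m, k])`` — conditional on the monthly totals
  this is exactly the multinomial model, and it makes the updates simple.
* Given the item, the foraging location is multinomial with a month-invariant
  item-specific law ``theta[k, l] = P(location l | item k)``, shared by
  identified and unidentified episodes.  This is what lets locations inform
  the imputation: identifiability varies with location, so the observed
  location of an unidentified episode is evidence about its item.
* Expected frequencies are seasonally autocorrelated: ``log lambda[:, k]``
  follows a circular first-order Gaussian random walk over the 12-month
  cycle (December adjacent to January) with a single item-specific precision
  ``tau[k]`` — the smoothing strength does not vary from month to month.

Priors: ``theta[k] ~ Dirichlet(alpha)``, ``tau[k] ~ Gamma(a_tau, b_tau)``,
and a Normal(mu0, s0^2) prior on the mean log level of each item's cycle
(which makes the intrinsic random walk proper).

Inference is Gibbs sampling with three blocks: multinomial reallocation of
unidentified episodes, conjugate Dirichlet updates of ``theta``, and
Metropolis-within-Gibbs updates of ``log lambda`` with a conjugate Gamma
update of ``tau``.

The *model-aided observation proportion* (MOP) of item ``k`` in month ``m``
is obtained from the posterior mean of the complete count ``n[m, k]``
(identified plus imputed), rounded half-away-from-zero to an integer and
renormalised within the month.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .composition import CompositionTable
from .episodes import CountsTensor
from .rop import rop_identified_only
from .schema import UNIDENTIFIED, N_MONTHS, CategorySchema


class DegenerateModelError(ValueError):
    """The model inputs or state admit no valid update."""


@dataclass(frozen=True)
class MopModelSpec:
    """Priors and sampler settings for the diet-imputation model.

    Parameters
    ----------
    dirichlet_alpha
        Symmetric Dirichlet concentration for each location-given-item row.
    level_prior_mean
        Prior mean mu0 of the per-item mean log frequency.  ``None`` (the
        default) resolves at fit time to ``log(mean monthly identified count
        per item + 0.5)``, a weakly data-scaled centre.
    level_prior_sd
        Prior standard deviation s0 of the mean log level.
    tau_shape, tau_rate
        Gamma(shape, rate) prior on each item's random-walk precision; the
        prior mean ``shape/rate`` sets the default smoothing strength.
    chains, iterations, burn_in, thinning
        MCMC schedule; ``iterations`` counts post-initialisation sweeps per
        chain, of which the first ``burn_in`` are discarded and the rest
        kept every ``thinning``-th.
    proposal_sd
        Gaussian random-walk proposal scale for the log-frequency updates.
    seed
        Master seed; per-chain streams are spawned from it, so a fit is
        bitwise reproducible.
    """

    dirichlet_alpha: float = 1.0
    level_prior_mean: float | None = None
    level_prior_sd: float = 2.0
    tau_shape: float = 2.0
    tau_rate: float = 0.5
    chains: int = 3
    iterations: int = 20_000
    burn_in: int = 10_000
    thinning: int = 10
    proposal_sd: float = 0.3
    seed: int = 0
    rhat_warn: float = 1.1

    def __post_init__(self) -> None:
        for name in ("dirichlet_alpha", "level_prior_sd", "tau_shape",
                     "tau_rate", "proposal_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.chains < 1 or self.thinning < 1:
            raise ValueError("chains and thinning must be >= 1")
        if not self.iterations > self.burn_in >= 0:
            raise ValueError("need iterations > burn_in >= 0")


@dataclass
class ModelData:
    """Sufficient statistics the sampler runs on (one species)."""

    y: np.ndarray            # (12, K, L) identified counts
    u: np.ndarray            # (12, L) unidentified-item counts
    totals_by_month: np.ndarray  # (12,) N_m
    schema: CategorySchema
    species: str

    @property
    def n_items(self) -> int:
        return self.y.shape[1]

    @property
    def n_locations(self) -> int:
        return self.y.shape[2]


def build_inputs(counts: CountsTensor) -> ModelData:
    """Split a counts tensor into identified counts and the unidentified
    margin the sampler reallocates."""
    if counts.total == 0:
        raise DegenerateModelError("all-zero counts tensor: nothing to fit")
    schema = counts.schema
    uidx = schema.unidentified_item_index
    keep = [i for i in range(schema.n_items) if i != uidx]
    y = counts.counts[:, keep, :]
    u = counts.counts[:, uidx, :]
    return ModelData(
        y=y.astype(np.int64),
        u=u.astype(np.int64),
        totals_by_month=counts.totals_by_month,
        schema=schema,
        species=counts.species,
    )


# ---------------------------------------------------------------------------
# Gibbs kernels
# ---------------------------------------------------------------------------

def sample_latent_items(
    pi: np.ndarray, theta: np.ndarray, u: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Reallocate unidentified episodes to identified items.

    Episodes are exchangeable within a (month, location) cell, so the latent
    labels are drawn in count form: the ``u[m, l]`` unidentified episodes of
    cell ``(m, l)`` are split multinomially over items with probabilities

        P(item k | month m, location l) ∝ pi[m, k] * theta[k, l].

    Returns the latent counts ``w`` with shape ``(12, K, L)``.
    """
    n_months, n_items = pi.shape
    n_loc = theta.shape[1]
    w = np.zeros((n_months, n_items, n_loc), dtype=np.int64)
    for m, l in zip(*np.nonzero(u)):
        p = pi[m] * theta[:, l]
        total = p.sum()
        if total <= 0 or not np.isfinite(total):
            raise DegenerateModelError(
                f"no item can produce location index {l} (theta column is zero)"
            )
        w[m, :, l] = rng.multinomial(u[m, l], p / total)
    return w


# alias emphasising the count representation
sample_latent_counts = sample_latent_items


def sample_theta(
    alpha: float, location_counts: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Conjugate Dirichlet draw of the location-given-item rows.

    ``location_counts`` holds the complete (identified + latent) location
    tallies per item, shape ``(K, L)``.
    """
    g = rng.gamma(alpha + location_counts)
    return g / g.sum(axis=1, keepdims=True)


def _tau_full_conditional(
    x: np.ndarray, shape: float, rate: float, rng: np.random.Generator
) -> np.ndarray:
    """Gamma draw of the circular random-walk precisions.

    The 12-cycle graph Laplacian has rank 11, so each item contributes
    tau^(11/2) exp(-tau * SS / 2) with SS the sum of squared circular
    month-to-month increments.
    """
    ss = ((np.roll(x, -1, axis=0) - x) ** 2).sum(axis=0)
    return rng.gamma(shape + (N_MONTHS - 1) / 2.0, 1.0 / (rate + ss / 2.0))


def sample_lambda(
    x: np.ndarray,
    n: np.ndarray,
    tau: np.ndarray,
    mu0: np.ndarray,
    s0: float,
    proposal_sd: float,
    rng: np.random.Generator,
    likelihood_mask: np.ndarray | None = None,
    tau_prior: tuple[float, float] | None = None,
) -> tuple[np.ndarray, np.ndarray, int]:
    """One Metropolis-within-Gibbs sweep over ``log lambda``, optionally
    followed by the conjugate Gamma update of the random-walk precisions.

    Parameters
    ----------
    x
        Current ``log lambda``, shape ``(12, K)``; updated copy returned.
    n
        Complete item counts per month, shape ``(12, K)``.
    tau
        Current per-item precisions, shape ``(K,)``.
    mu0, s0
        Mean-level prior: per-item prior mean (shape ``(K,)`` or scalar) and
        common prior sd of ``mean_m log lambda[m, k]``.
    likelihood_mask
        Boolean per month; months with no episodes contribute no likelihood
        (their log frequency is interpolated by the prior alone).
    tau_prior
        ``(shape, rate)`` of the Gamma prior on tau; when given, tau is
        redrawn from its full conditional under the updated ``x``.

    Returns ``(x, tau, n_accepted)``.
    """
    x = x.copy()
    n_months, n_items = x.shape
    if likelihood_mask is None:
        likelihood_mask = np.ones(n_months, dtype=bool)
    mu0 = np.broadcast_to(np.asarray(mu0, dtype=float), (n_items,))
    accepted = 0
    means = x.mean(axis=0)
    for m in range(n_months):
        prev, nxt = (m - 1) % n_months, (m + 1) % n_months
        prop = x[m] + proposal_sd * rng.standard_normal(n_items)
        d = prop - x[m]
        if likelihood_mask[m]:
            # Poisson: n log(lam) - lam, lam = exp(x)
            dlik = n[m] * d - (np.exp(prop) - np.exp(x[m]))
        else:
            dlik = np.zeros(n_items)
        drw = -0.5 * tau * (
            (prop - x[prev]) ** 2 + (prop - x[nxt]) ** 2
            - (x[m] - x[prev]) ** 2 - (x[m] - x[nxt]) ** 2
        )
        new_means = means + d / n_months
        dlevel = -((new_means - mu0) ** 2 - (means - mu0) ** 2) / (2.0 * s0 * s0)
        log_ratio = dlik + drw + dlevel
        if np.isnan(log_ratio).any():
            raise FloatingPointError(
                "non-finite acceptance ratio in log-frequency update; "
                "check proposal_sd and priors"
            )
        accept = np.log(rng.random(n_items)) < log_ratio
        x[m, accept] = prop[accept]
        means = np.where(accept, new_means, means)
        accepted += int(accept.sum())
    if tau_prior is not None:
        tau = _tau_full_conditional(x, tau_prior[0], tau_prior[1], rng)
    return x, tau, accepted


def _softmax_rows(x: np.ndarray) -> np.ndarray:
    z = x - x.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

class DietImputationModel:
    """Bayesian imputation model for unidentified diet items of one species.

    Parameters
    ----------
    counts
        The species' monthly ``[month, item, location]`` count tensor.
    spec
        Priors and sampler settings; defaults to :class:`MopModelSpec`.

    Examples
    --------
    >>> model = DietImputationModel(counts)
    >>> results = model.fit()
    >>> results.mop().to_frame()
    """

    def __init__(self, counts: CountsTensor, spec: MopModelSpec | None = None):
        self.spec = spec or MopModelSpec()
        self.counts = counts
        self.data = build_inputs(counts)

    @classmethod
    def from_episodes(
        cls,
        episodes,
        species: str,
        schema: CategorySchema | None = None,
        spec: MopModelSpec | None = None,
    ) -> "DietImputationModel":
        """Build the model directly from a filtered episode list."""
        from .episodes import tally

        return cls(tally(episodes, species, schema), spec=spec)

    # -- initial state ------------------------------------------------------

    def _mu0(self) -> float:
        if self.spec.level_prior_mean is not None:
            return float(self.spec.level_prior_mean)
        mean_monthly = self.data.y.sum() / (N_MONTHS * self.data.n_items)
        return float(np.log(mean_monthly + 0.5))

    def _initial_state(self, rng: np.random.Generator):
        d, spec = self.data, self.spec
        item_totals = self.data.y.sum(axis=2)          # (12, K)
        x = np.log(item_totals + 0.5) + 0.1 * rng.standard_normal(item_totals.shape)
        theta = sample_theta(spec.dirichlet_alpha, d.y.sum(axis=0), rng)
        tau = np.full(d.n_items, spec.tau_shape / spec.tau_rate)
        return x, theta, tau

    # -- sampling -----------------------------------------------------------

    def _run_chain(self, rng: np.random.Generator) -> dict[str, np.ndarray]:
        d, spec = self.data, self.spec
        mu0 = self._mu0()
        mask = d.totals_by_month > 0
        x, theta, tau = self._initial_state(rng)
        n_keep = (spec.iterations - spec.burn_in) // spec.thinning
        draws = {
            "log_lambda": np.empty((n_keep, N_MONTHS, d.n_items)),
            "theta": np.empty((n_keep, d.n_items, d.n_locations)),
            "tau": np.empty((n_keep, d.n_items)),
            "complete_counts": np.empty((n_keep, N_MONTHS, d.n_items), dtype=np.int64),
        }
        accepted = 0
        kept = 0
        y_items = d.y.sum(axis=2)  # (12, K)
        for it in range(spec.iterations):
            pi = _softmax_rows(x)
            w = sample_latent_items(pi, theta, d.u, rng)
            complete_loc = (d.y + w).sum(axis=0)           # (K, L)
            n = y_items + w.sum(axis=2)                     # (12, K)
            theta = sample_theta(spec.dirichlet_alpha, complete_loc, rng)
            x, tau, acc = sample_lambda(
                x, n, tau, mu0, spec.level_prior_sd, spec.proposal_sd, rng,
                likelihood_mask=mask,
                tau_prior=(spec.tau_shape, spec.tau_rate),
            )
            accepted += acc
            if it >= spec.burn_in and (it - spec.burn_in) % spec.thinning == 0:
                if kept < n_keep:
                    draws["log_lambda"][kept] = x
                    draws["theta"][kept] = theta
                    draws["tau"][kept] = tau
                    draws["complete_counts"][kept] = n
                    kept += 1
        draws["acceptance_rate"] = accepted / (spec.iterations * N_MONTHS * d.n_items)
        return draws

    def fit(self) -> "DietImputationResults":
        """Run the Gibbs sampler and return the posterior results."""
        spec = self.spec
        streams = np.random.SeedSequence(spec.seed).spawn(spec.chains)
        chains = [self._run_chain(np.random.default_rng(s)) for s in streams]
        draws = {
            key: np.stack([c[key] for c in chains])
            for key in ("log_lambda", "theta", "tau", "complete_counts")
        }
        acceptance = float(np.mean([c["acceptance_rate"] for c in chains]))
        return DietImputationResults(self, draws, acceptance)


def fit_mop(counts: CountsTensor, spec: MopModelSpec | None = None) -> "DietImputationResults":
    """Functional wrapper: fit the imputation model to one species' counts."""
    return DietImputationModel(counts, spec=spec).fit()


class DietImputationResults:
    """Posterior draws, diagnostics and MOPs from a fitted imputation model.

    Attributes
    ----------
    draws
        Dict of arrays with a leading ``(chain, draw)`` index:
        ``log_lambda`` (12 x K), ``theta`` (K x L), ``tau`` (K,) and the
        integer ``complete_counts`` (12 x K; identified + imputed, summing
        to the month's episode total in every draw).
    acceptance_rate
        Mean Metropolis acceptance rate of the log-frequency updates.
    """

    def __init__(self, model: DietImputationModel, draws: dict, acceptance_rate: float):
        self.model = model
        self.draws = draws
        self.acceptance_rate = acceptance_rate
        self._diagnostics: pd.DataFrame | None = None
        # episode conservation: every draw reallocates exactly the observed
        # unidentified episodes
        totals = draws["complete_counts"].sum(axis=-1)
        expected = model.data.totals_by_month
        if not np.array_equal(
            totals, np.broadcast_to(expected, totals.shape)
        ):
            raise AssertionError("episode conservation violated in draws")

    @property
    def spec(self) -> MopModelSpec:
        return self.model.spec

    @property
    def complete_counts_mean(self) -> np.ndarray:
        """Posterior-mean complete item counts, shape (12, K)."""
        return self.draws["complete_counts"].mean(axis=(0, 1))

    @property
    def pi_mean(self) -> np.ndarray:
        """Posterior-mean monthly item distribution implied by lambda."""
        lam = np.exp(self.draws["log_lambda"])
        pi = lam / lam.sum(axis=-1, keepdims=True)
        return pi.mean(axis=(0, 1))

    @property
    def theta_mean(self) -> np.ndarray:
        return self.draws["theta"].mean(axis=(0, 1))

    def mop(self) -> CompositionTable:
        """Model-aided observation proportions (see :func:`compute_mop`)."""
        return compute_mop(self)

    # -- diagnostics --------------------------------------------------------

    def diagnostics(self) -> pd.DataFrame:
        """Split-R̂ and effective sample size per scalar parameter."""
        if self._diagnostics is None:
            import arviz as az

            idata = az.from_dict(
                posterior={
                    "log_lambda": self.draws["log_lambda"],
                    "theta": self.draws["theta"],
                    "tau": self.draws["tau"],
                }
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rhat = az.rhat(idata)
                ess = az.ess(idata)
            rows = []
            for name in ("log_lambda", "theta", "tau"):
                r = np.asarray(rhat[name]).ravel()
                e = np.asarray(ess[name]).ravel()
                for j, (ri, ei) in enumerate(zip(r, e)):
                    rows.append({"parameter": f"{name}[{j}]", "rhat": ri, "ess": ei})
            self._diagnostics = pd.DataFrame(rows)
            max_rhat = self._diagnostics["rhat"].max()
            if self.spec.chains > 1 and max_rhat > self.spec.rhat_warn:
                warnings.warn(
                    f"max split-R-hat {max_rhat:.3f} exceeds "
                    f"{self.spec.rhat_warn}; consider more iterations",
                    stacklevel=2,
                )
        return self._diagnostics

    def summary(self) -> str:
        """Plain-text fit summary: data size, sampler settings, convergence
        and the monthly MOP table."""
        d = self.model.data
        spec = self.spec
        n_total = int(d.totals_by_month.sum())
        n_unid = int(d.u.sum())
        lines = [
            "Diet imputation model" ,
            "=" * 60,
            f"species:              {d.species}",
            f"episodes:             {n_total} ({n_unid} unidentified, "
            f"{n_unid / n_total:.1%})",
            f"items x locations:    {d.n_items} x {d.n_locations}",
            f"chains/iter/burn/thin: {spec.chains}/{spec.iterations}/"
            f"{spec.burn_in}/{spec.thinning}",
            f"MH acceptance rate:   {self.acceptance_rate:.3f}",
        ]
        if spec.chains > 1:
            diag = self.diagnostics()
            lines.append(
                f"max split-R-hat:      {diag['rhat'].max():.3f}   "
                f"min ESS: {diag['ess'].min():.0f}"
            )
        lines.append("")
        lines.append("Model-aided observation proportions (MOP):")
        lines.append(self.mop().to_frame().round(3).to_string())
        return "\n".join(lines)


def compute_mop(results: DietImputationResults) -> CompositionTable:
    """MOPs from a fitted model: round the posterior-mean complete count of
    each item half-away-from-zero to an integer, then normalise each month.

    When the data contain no unidentified episodes the complete counts are
    the observed integer counts in every draw, and the MOP coincides exactly
    with the identified-only ROP.
    """
    d = results.model.data
    mean_counts = results.complete_counts_mean
    rounded = np.floor(mean_counts + 0.5)  # half away from zero; counts >= 0
    return CompositionTable.from_counts(
        species=d.species,
        kind="MOP",
        counts=rounded,
        categories=d.schema.identified_items,
    )
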