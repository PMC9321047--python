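"""Correlated-random-walk (Markov) movement model for tracked foci.

The model treats each step of a focus as partially correlated with the
previous one:

    y_{t+1} = y_t + gamma * T(theta) * d_{t-1} + eps_t

where ``y_t`` is the 3D position, ``d_{t-1} = y_t - y_{t-1}`` the previous
movement vector, ``gamma`` the degree of directional autocorrelation with
that vector (0 = random walk, 1 = perfectly directed), ``T`` a rotation by
the mean turn angle ``theta``, and ``eps_t`` an isotropic Gaussian
random-walk displacement of per-axis scale ``sigma`` (movement
variability).

In three dimensions a single rotation angle does not determine a rotation
matrix (the axis is unspecified), so estimation sets ``T`` to the identity
and absorbs systematic turning into the residual; the mean turn angle is
reported descriptively from :func:`turning_angles`.  A single behavioural
state is fitted per trajectory — no state switching.

Estimation is conditional least squares (CLS) without intercept, pooling
the x, y and z components of each (d_t, d_{t-1}) pair.  Under isotropic
Gaussian residuals this coincides with maximum likelihood and admits the
closed form

    gamma_hat = sum_t d_t . d_{t-1}  /  sum_t |d_{t-1}|^2,

which the test suite uses as an independent oracle.  ``sigma`` is the
root-mean-square residual norm per step divided by sqrt(3), i.e. a
per-axis standard deviation in μm per step.

Anisotropic sampling (axial z steps coarser than lateral) is not
corrected; when axial extents are known to exceed lateral ones the caller
should interpret ``sigma`` cautiously.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .exceptions import ValidationError
from .kinematics import step_vectors
from .trajectory_io import Trajectory

logger = logging.getLogger(__name__)

#: Directional-correlation threshold above which movement is called directed.
DEFAULT_RANDOMNESS_THRESHOLD = 0.5


@dataclass
class MovementFit:
    """Estimated movement-model parameters for one trajectory.

    Attributes
    ----------
    gamma
        Directional correlation with the previous movement vector,
        dimensionless in [-1, 1] (up to sampling noise).
    gamma_se
        Standard error of ``gamma`` from the pooled regression.
    theta_mean
        Mean 3D turn angle between consecutive displacement vectors,
        radians in [0, pi]; NaN if no nonzero consecutive pairs exist.
    sigma
        Random-walk displacement scale: per-axis residual standard
        deviation, μm per step.
    n_steps
        Number of displacement vectors entering the fit.
    """

    focus_id: str
    gamma: float
    gamma_se: float
    theta_mean: float
    sigma: float
    n_steps: int
    label: str = ""

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValidationError("sigma must be nonnegative")
        if abs(self.gamma) > 1 + 1e-6:
            logger.warning(
                "focus %s: |gamma| = %.3f exceeds 1; sampling noise or "
                "model misfit",
                self.focus_id,
                abs(self.gamma),
            )


def _consecutive_step_pairs(traj: Trajectory) -> tuple[np.ndarray, np.ndarray]:
    """(d_{t-1}, d_t) vector pairs from frame triples with no gap."""
    idx, vecs, _ = step_vectors(traj)
    follow = np.nonzero(np.diff(idx) == 1)[0]
    if follow.size < 2:
        raise ValidationError(
            f"trajectory {traj.focus_id!r}: need >= 2 consecutive "
            "displacement pairs (>= 4 gap-free frames)"
        )
    return vecs[follow], vecs[follow + 1]


def fit_markov_model(traj: Trajectory) -> MovementFit:
    """Fit the movement model to one trajectory by pooled CLS.

    Each displacement vector ``d_t`` is regressed (no intercept) on its
    predecessor ``d_{t-1}``, pooling the three spatial components.  Pairs
    spanning a gap are excluded.

    Raises
    ------
    ValidationError
        If fewer than 4 gap-free frames are available, or if all
        displacements are zero (gamma is then undefined, not 0).
    """
    prev, curr = _consecutive_step_pairs(traj)
    x = prev.ravel()
    y = curr.ravel()
    sxx = float(x @ x)
    if sxx == 0.0:
        raise ValidationError(
            f"trajectory {traj.focus_id!r}: all displacements zero; "
            "gamma is undefined"
        )
    coef, *_ = np.linalg.lstsq(x[:, None], y, rcond=None)
    gamma = float(coef[0])
    resid = y - gamma * x
    rss = float(resid @ resid)
    n_obs = y.size
    dof = max(n_obs - 1, 1)
    gamma_se = float(np.sqrt(rss / dof / sxx))
    # rms residual norm per step, scaled to a per-axis standard deviation
    sigma = float(np.sqrt(rss / prev.shape[0]) / np.sqrt(3.0))
    _, vecs, _ = step_vectors(traj)
    angles = _turning_angles_from_vectors(traj)
    theta_mean = float(np.mean(angles)) if angles.size else float("nan")
    return MovementFit(
        focus_id=traj.focus_id,
        gamma=gamma,
        gamma_se=gamma_se,
        theta_mean=theta_mean,
        sigma=sigma,
        n_steps=int(vecs.shape[0]),
        label=traj.label,
    )


def _turning_angles_from_vectors(traj: Trajectory) -> np.ndarray:
    idx, vecs, _ = step_vectors(traj)
    follow = np.nonzero(np.diff(idx) == 1)[0]
    angles = []
    for k in follow:
        a, b = vecs[k], vecs[k + 1]
        na, nb = np.linalg.norm(a), np.linalg.norm(b)
        if na == 0 or nb == 0:  # zero-length steps carry no direction
            continue
        cosang = np.clip(a @ b / (na * nb), -1.0, 1.0)
        angles.append(np.arccos(cosang))
    return np.asarray(angles)


def turning_angles(traj: Trajectory) -> np.ndarray:
    """3D turn angles (radians, in [0, pi]) between consecutive steps.

    Zero-length displacements are skipped.  Requires at least two usable
    consecutive displacement pairs.
    """
    angles = _turning_angles_from_vectors(traj)
    if angles.size < 2:
        raise ValidationError(
            f"trajectory {traj.focus_id!r}: fewer than 2 usable "
            "consecutive displacement pairs"
        )
    return angles


def classify_randomness(
    fit: MovementFit, threshold: float = DEFAULT_RANDOMNESS_THRESHOLD
) -> str:
    """Label a fit ``"random"`` (gamma < threshold) or ``"directed"``.

    The boundary is strict-below for random: gamma exactly at the
    threshold is classified directed.
    """
    return "random" if fit.gamma < threshold else "directed"
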