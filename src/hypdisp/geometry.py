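"""Hyperbolic-disk geometry: the law-of-cosines distance, rotational alignment
of embeddings to a common reference, and the per-node displacement (HypDisp)
score between an original and a perturbed embedding.

Conventions
-----------
Points live on the (rescaled, unit-radius) hyperbolic disk in polar form
``(r, theta)`` with ``r >= 0`` and ``theta`` wrapped to ``[0, 2*pi)``.  The
distance between two points follows the hyperbolic law of cosines,

    cosh d = cosh r_a cosh r_b - sinh r_a sinh r_b cos(Dtheta),

where ``Dtheta = pi - |pi - |theta_a - theta_b||`` is the angular separation
along the shorter arc.  Alignment rotates (and optionally reflects) a whole
embedding so that the summed displacement to a reference embedding is
minimal; radii are never altered by alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

TWO_PI = 2.0 * np.pi


def wrap_angle(theta):
    """Wrap angles to ``[0, 2*pi)``."""
    return np.mod(theta, TWO_PI)


def angular_separation(theta_a, theta_b):
    """Shorter-arc angular separation ``pi - |pi - |a - b||`` in [0, pi]."""
    return np.pi - np.abs(np.pi - np.abs(np.asarray(theta_a) - np.asarray(theta_b)))


def hyperbolic_distance(r_a, theta_a, r_b, theta_b):
    """Hyperbolic law-of-cosines distance between polar points on the disk.

    Vectorized over numpy broadcastable inputs.  Evaluated in the
    cancellation-free form

        cosh d - 1 = 2 sinh^2((r_a - r_b)/2) + 2 sinh r_a sinh r_b sin^2(Dtheta/2)

    (algebraically identical to the law of cosines) with a log1p-based
    arccosh, so nearby points keep full relative precision: ``d(a, a) == 0``
    exactly and collinear pairs return ``|r_a - r_b|`` to machine accuracy.
    """
    r_a = np.asarray(r_a, dtype=float)
    r_b = np.asarray(r_b, dtype=float)
    dtheta = angular_separation(theta_a, theta_b)
    y = (
        2.0 * np.sinh((r_a - r_b) / 2.0) ** 2
        + 2.0 * np.sinh(r_a) * np.sinh(r_b) * np.sin(dtheta / 2.0) ** 2
    )
    # arccosh(1 + y) without forming 1 + y
    return np.log1p(y + np.sqrt(y * (y + 2.0)))


@dataclass
class AlignmentResult:
    """Outcome of aligning one embedding to a reference."""

    rotation: float  # angle added to every node, radians
    reflected: bool  # whether theta -> (2*pi - theta) was applied first
    loss: float  # summed hyperbolic displacement to the reference at optimum
    loss_identity: float  # loss of the untransformed embedding, for auditing


def _rotation_loss(ref_r, ref_theta, r, theta, phis):
    """Loss L(phi) = sum_i d_hyp(ref_i, rotate(emb, phi)_i) for many phis."""
    theta_rot = theta[None, :] + np.asarray(phis)[:, None]
    d = hyperbolic_distance(ref_r[None, :], ref_theta[None, :], r[None, :], theta_rot)
    return d.sum(axis=1)


def _golden_section(fun, a, b, tol=1e-9, max_iter=200):
    invphi = (np.sqrt(5.0) - 1.0) / 2.0
    c = b - invphi * (b - a)
    d = a + invphi * (b - a)
    fc, fd = fun(c), fun(d)
    it = 0
    while abs(b - a) > tol and it < max_iter:
        if fc < fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = fun(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = fun(d)
        it += 1
    x = (a + b) / 2.0
    return x, fun(x)


def find_rotation(
    ref_r: np.ndarray,
    ref_theta: np.ndarray,
    r: np.ndarray,
    theta: np.ndarray,
    n_grid: int = 1024,
    tol: float = 1e-9,
    allow_reflection: bool = True,
) -> AlignmentResult:
    """Find the rotation (and optional reflection) minimizing the summed
    hyperbolic displacement to a reference embedding.

    The loss can be multimodal, so a coarse grid of ``n_grid`` rotations is
    scanned first and the best bracket is refined by golden-section search
    (tight tolerance: the loss is V-shaped in the rotation angle near the
    optimum, so the residual loss scales like N times the angle error).
    The reflection ``theta -> (2*pi - theta) mod 2*pi`` is evaluated as well
    (dimensional projections can flip chirality between networks) and kept
    only if it achieves a strictly lower loss.
    """
    ref_r = np.asarray(ref_r, dtype=float)
    ref_theta = np.asarray(ref_theta, dtype=float)
    r = np.asarray(r, dtype=float)
    theta = np.asarray(theta, dtype=float)
    if ref_r.shape != r.shape:
        raise ValueError("embedding and reference must have the same node count")

    phis = np.linspace(0.0, TWO_PI, n_grid, endpoint=False)
    step = TWO_PI / n_grid
    loss_id = float(_rotation_loss(ref_r, ref_theta, r, theta, [0.0])[0])

    candidates = [(theta, False)]
    if allow_reflection:
        candidates.append((wrap_angle(TWO_PI - theta), True))

    best = None
    for th, refl in candidates:
        grid_losses = _rotation_loss(ref_r, ref_theta, r, th, phis)
        j = int(np.argmin(grid_losses))

        def f(phi, _th=th):
            return float(_rotation_loss(ref_r, ref_theta, r, _th, [phi])[0])

        phi_star, loss = _golden_section(f, phis[j] - step, phis[j] + step, tol=tol)
        if best is None or loss < best.loss:
            best = AlignmentResult(
                rotation=float(np.mod(phi_star, TWO_PI)),
                reflected=refl,
                loss=float(loss),
                loss_identity=loss_id,
            )
    return best


def apply_transform(theta: np.ndarray, result: AlignmentResult) -> np.ndarray:
    """Apply an alignment transform (reflection then rotation) to angles."""
    theta = np.asarray(theta, dtype=float)
    if result.reflected:
        theta = wrap_angle(TWO_PI - theta)
    return wrap_angle(theta + result.rotation)


def hypdisp_scores(
    r_pre: np.ndarray,
    theta_pre: np.ndarray,
    r_post: np.ndarray,
    theta_post: np.ndarray,
) -> np.ndarray:
    """Per-node hyperbolic displacement between two aligned embeddings.

    ``HypDisp(i) = d_hyp(Pos_o(i), Pos_p(i))`` where the original (pre) and
    perturbed (post) embeddings must share node order and have been aligned
    to the same reference.
    """
    r_pre = np.asarray(r_pre, dtype=float)
    r_post = np.asarray(r_post, dtype=float)
    if r_pre.shape != r_post.shape:
        raise ValueError("pre and post embeddings must have matching node counts")
    return hyperbolic_distance(r_pre, theta_pre, r_post, theta_post)


def circular_correlation(a: np.ndarray, b: np.ndarray) -> float:
    """Fisher-Lee circular correlation between two angle vectors.

    Invariant to independent rotations of either input; its sign flips under
    reflection of one input, so callers interested only in angular-order
    recovery use the absolute value.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ii, jj = np.triu_indices(a.size, k=1)
    sa = np.sin(a[ii] - a[jj])
    sb = np.sin(b[ii] - b[jj])
    denom = np.sqrt(np.sum(sa**2) * np.sum(sb**2))
    if denom == 0:
        return 0.0
    return float(np.sum(sa * sb) / denom)
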