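"""Pulse-coupled neural network dynamics and adaptive parameterization.

One neuron per pixel. Each iteration: feeding F is the (blur-masked)
input, linking L is the 3x3-weighted sum of last iteration's pulses,
internal activity U = F * (1 + delta * L), and the dynamic threshold E
decays exponentially (factor exp(-F_E)) from its initialization, jumping
to an effectively infinite value after a neuron fires so firing happens
exactly once per run. The decay is floored at Td_min; when the floor is
reached, every neuron that has not yet fired pulses, which guarantees
termination even for zero-intensity (masked) pixels.

The decay factor F_E, judgment criterion C, and linking strength delta
are estimated from gray-level statistics of three gradient-magnitude
populations (low/mid/high-frequency terciles):

    F_E   = ln((M_LF + s_LF) / (M_LF - s_LF))
    C     = min(8, (1 / F_E) * ln((M_HF + s_HF) / (M_HF - s_HF)))
    delta = 3 * s_LF / (C * (M_LF - s_LF))

Td_min is the 6th percentile of the normalized gray image, so at least
94% of pixels lie in [Td_min, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import (
    ConvergenceError,
    DegenerateStatsError,
    InvalidImageError,
    InvalidParameterError,
)
from .ltp import BlurMaskedImage

__all__ = [
    "BandStats",
    "PcnnParams",
    "PcnnState",
    "EdgeMap",
    "DEFAULT_KERNEL",
    "band_stats",
    "estimate_params",
    "init_state",
    "pcnn_step",
    "pcnn_run",
    "binarize_and_clean",
]

#: 3x3 linking kernel: edge-adjacent weight 1, diagonal 0.5, center 0.
DEFAULT_KERNEL = np.array([[0.5, 1.0, 0.5], [1.0, 0.0, 1.0], [0.5, 1.0, 0.5]])

#: Refractory amplitude: larger than any attainable internal activity.
V_E_SENTINEL = 1e12

_STRUCT8 = np.ones((3, 3), dtype=bool)  # 8-connectivity, matches the kernel reach


@dataclass
class BandStats:
    """Gray-level mean/std of the low/mid/high-frequency pixel populations."""

    m_lf: float
    m_mf: float
    m_hf: float
    sigma_lf: float
    sigma_mf: float
    sigma_hf: float


@dataclass
class PcnnParams:
    w_con: np.ndarray = field(default_factory=lambda: DEFAULT_KERNEL.copy())
    delta: float = 1.0
    theta_e: np.ndarray | float = 1.0  # per-pixel init (gamma) or scalar max
    f_e: float = 0.5
    v_e: float = V_E_SENTINEL
    td_min: float = 0.05
    c: float = 1.0
    q_l: float = 1.0
    max_iters: int = 256
    literal_firing_rule: bool = False  # archaeology only; see pcnn_step

    def __post_init__(self):
        if self.f_e <= 0:
            raise InvalidParameterError("f_e must be > 0")
        if not 0 <= self.c <= 8:
            raise InvalidParameterError("c must lie in [0, 8]")
        if self.delta <= 0:
            raise InvalidParameterError("delta must be > 0")
        if not 0 < self.td_min < 1:
            raise InvalidParameterError("td_min must lie in (0, 1)")

    def to_dict(self) -> dict:
        theta = self.theta_e
        return {
            "delta": self.delta,
            "f_e": self.f_e,
            "c": self.c,
            "td_min": self.td_min,
            "q_l": self.q_l,
            "v_e": self.v_e,
            "max_iters": self.max_iters,
            "theta_e": "per-pixel" if np.ndim(theta) else float(theta),
            "w_con": np.asarray(self.w_con).tolist(),
        }


@dataclass
class PcnnState:
    f: np.ndarray  # feeding
    l: np.ndarray  # linking
    u: np.ndarray  # internal activity
    e: np.ndarray  # dynamic threshold
    y: np.ndarray  # binary pulse output of the current iteration
    fired: np.ndarray  # iteration index of first firing, 0 = not yet
    n: int = 0  # iterations completed
    y_natural: np.ndarray | None = None  # subset of y that crossed U >= E


@dataclass
class EdgeMap:
    m_edge: np.ndarray  # accumulated wave-boundary evidence (binary)
    labels: np.ndarray  # component id per pixel, unique across waves
    p_con: np.ndarray  # count of 8-neighbors firing in the same wave
    first_wave: np.ndarray  # pixels that fired in iteration 1


def band_stats(img: np.ndarray) -> BandStats:
    """Partition pixels into local-variation terciles and report the
    gray-level mean/std of each population (low variation -> LF).

    Local variation is the 3x3 range (max - min), which — unlike a Sobel
    gradient — responds to single-pixel alternation (the highest
    representable spatial frequency).
    """
    arr = np.asarray(img, dtype=np.float64)
    if arr.ndim != 2 or min(arr.shape) < 3:
        raise InvalidImageError("band_stats needs a 2-D image at least 3x3")
    grad = (
        ndimage.maximum_filter(arr, size=3, mode="nearest")
        - ndimage.minimum_filter(arr, size=3, mode="nearest")
    ).ravel()
    order = np.argsort(grad, kind="stable")
    vals = arr.ravel()[order]
    thirds = np.array_split(vals, 3)
    means = [float(t.mean()) for t in thirds]
    sigmas = [float(t.std()) for t in thirds]
    return BandStats(means[0], means[1], means[2], sigmas[0], sigmas[1], sigmas[2])


def estimate_params(img: np.ndarray, stats: BandStats | None = None, **overrides) -> PcnnParams:
    """Derive the adaptive parameters from band statistics of ``img``.

    Raises :class:`DegenerateStatsError` when the statistics cannot
    support the closed forms (flat bands, or mean not exceeding std).
    """
    arr = np.asarray(img, dtype=np.float64)
    if stats is None:
        stats = band_stats(arr)
    if stats.m_lf - stats.sigma_lf <= 0 or stats.m_hf - stats.sigma_hf <= 0:
        raise DegenerateStatsError(
            "band mean must exceed band std in the LF and HF populations "
            f"(got M_LF={stats.m_lf:.4g}, s_LF={stats.sigma_lf:.4g}, "
            f"M_HF={stats.m_hf:.4g}, s_HF={stats.sigma_hf:.4g})"
        )
    if stats.sigma_lf == 0:
        raise DegenerateStatsError("zero LF variance: decay factor would vanish")
    f_e = float(np.log((stats.m_lf + stats.sigma_lf) / (stats.m_lf - stats.sigma_lf)))
    c = float(min(8.0, np.log((stats.m_hf + stats.sigma_hf) / (stats.m_hf - stats.sigma_hf)) / f_e))
    if c <= 0:
        raise DegenerateStatsError(
            "judgment criterion C is zero (no HF contrast); raise the ternary "
            "contrast of the input or supply parameters explicitly"
        )
    delta = float(3.0 * stats.sigma_lf / (c * (stats.m_lf - stats.sigma_lf)))
    td_min = float(np.quantile(arr, 0.06, method="lower"))
    # a zero floor would never release unfired zero-intensity neurons
    td_min = float(np.clip(td_min, 1e-3, 1 - 1e-9))
    kwargs = dict(
        delta=delta, theta_e=arr.copy(), f_e=f_e, td_min=td_min, c=c
    )
    kwargs.update(overrides)
    return PcnnParams(**kwargs)


def _as_input_array(inp) -> np.ndarray:
    if isinstance(inp, BlurMaskedImage):
        return np.asarray(inp.pixels, dtype=np.float64)
    return np.asarray(inp, dtype=np.float64)


def init_state(inp, params: PcnnParams) -> PcnnState:
    """Fresh state: E at its initialization field, no pulses, nothing fired."""
    arr = _as_input_array(inp)
    e0 = np.broadcast_to(np.asarray(params.theta_e, dtype=np.float64), arr.shape).copy()
    zeros = np.zeros_like(arr)
    return PcnnState(
        f=arr.copy(),
        l=zeros.copy(),
        u=zeros.copy(),
        e=e0,
        y=np.zeros(arr.shape, dtype=bool),
        fired=np.zeros(arr.shape, dtype=np.int32),
        n=0,
    )


def pcnn_step(state: PcnnState, params: PcnnParams, inp) -> PcnnState:
    """Advance one synchronous iteration in place and return the state.

    Firing uses the pulse rule Y = step(U - E) restricted to neurons that
    have not fired, with the floor-release: once the threshold has
    decayed to Td_min, all remaining neurons fire. The printed literal
    rule (fire when activity is *below* the floor) is available behind
    ``params.literal_firing_rule`` for archaeology; it is not used by
    any default path.
    """
    if state.fired is None or state.e is None:
        raise InvalidParameterError("uninitialized state")
    arr = _as_input_array(inp)
    n = state.n + 1
    state.f = arr
    state.l = params.q_l * ndimage.convolve(
        state.y.astype(np.float64), params.w_con, mode="constant", cval=0.0
    )
    state.u = state.f * (1.0 + params.delta * state.l)
    if n > 1:
        state.e = np.exp(-params.f_e) * state.e + params.v_e * state.y
        state.e = np.maximum(state.e, params.td_min)
    unfired = state.fired == 0
    if params.literal_firing_rule:
        fire = unfired & (state.u < params.td_min)
        state.y_natural = fire
    else:
        at_floor = state.e <= params.td_min
        natural = unfired & (state.u >= state.e)
        fire = natural | (unfired & at_floor)
        state.y_natural = natural
    state.y = fire
    state.fired[fire] = n
    state.n = n
    return state


def pcnn_run(inp, params: PcnnParams) -> tuple[EdgeMap, PcnnState]:
    """Iterate until every neuron has fired, accumulating wave structure.

    Each iteration's synchronously firing set is labeled into connected
    components (8-connectivity); boundary pixels of every wave accumulate
    into the edge map, and each pixel records how many of its 8 neighbors
    fired in the same wave (connectivity count).
    """
    arr = _as_input_array(inp)
    state = init_state(arr, params)
    m_edge = np.zeros(arr.shape, dtype=bool)
    labels = np.zeros(arr.shape, dtype=np.int32)
    p_con = np.zeros(arr.shape, dtype=np.int32)
    first_wave = np.zeros(arr.shape, dtype=bool)
    next_label = 0
    while (state.fired == 0).any():
        if state.n >= params.max_iters:
            raise ConvergenceError(
                f"{int((state.fired == 0).sum())} neurons unfired after "
                f"{params.max_iters} iterations",
                state=state,
                edge=EdgeMap(m_edge, labels, p_con, first_wave),
            )
        pcnn_step(state, params, arr)
        wave = state.y
        if not wave.any():
            continue
        if state.n == 1:
            first_wave = wave.copy()
        lbl, n_lbl = ndimage.label(wave, structure=_STRUCT8)
        labels[wave] = lbl[wave] + next_label
        next_label += n_lbl
        counts = ndimage.convolve(
            wave.astype(np.int32), np.ones((3, 3), dtype=np.int32),
            mode="constant", cval=0,
        ) - wave.astype(np.int32)
        p_con[wave] = counts[wave]
        # Edge evidence comes from threshold-crossing firings only:
        # floor-released neurons (zero-input pixels) fire in an order set
        # by their initial threshold, not by image structure, so their
        # wave boundaries carry no spatial information.
        natural = wave if state.y_natural is None else state.y_natural
        if natural.any():
            interior = ndimage.binary_erosion(
                natural, structure=_STRUCT8, border_value=0
            )
            m_edge |= natural & ~interior
    return EdgeMap(m_edge, labels, p_con, first_wave), state


def binarize_and_clean(
    edge: EdgeMap,
    td: float | None = None,
    *,
    min_size: int = 64,
    closing_iters: int = 2,
) -> np.ndarray:
    """Edge evidence -> final foreground mask (sharp = True).

    Threshold the edge map (adaptive 2x-mean when ``td`` is None), keep
    components touching the first firing wave, then morphological closing
    followed by hole-filling and small-object removal.
    """
    evidence = edge.m_edge.astype(np.float64)
    if td is None:
        td = 2.0 * float(evidence.mean())
    binary = evidence > td if td > 0 else evidence > 0
    if not binary.any():
        return np.zeros_like(binary)
    lbl, n_lbl = ndimage.label(binary, structure=_STRUCT8)
    if edge.first_wave.any():
        keep = np.unique(lbl[binary & edge.first_wave])
        keep = keep[keep > 0]
        binary = np.isin(lbl, keep)
    # closing with an outside-is-foreground erosion border so evidence
    # touching the image edge is not eaten away
    mask = ndimage.binary_dilation(
        binary, structure=_STRUCT8, iterations=closing_iters, border_value=0
    )
    mask = ndimage.binary_erosion(
        mask, structure=_STRUCT8, iterations=closing_iters, border_value=1
    )
    mask = ndimage.binary_fill_holes(mask)
    if min_size > 1:
        lbl, n_lbl = ndimage.label(mask, structure=_STRUCT8)
        if n_lbl:
            sizes = np.bincount(lbl.ravel())
            small = np.flatnonzero(sizes < min_size)
            mask[np.isin(lbl, small[small > 0])] = False
    return mask
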