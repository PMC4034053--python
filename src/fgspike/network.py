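"""Five-area feed-forward network: drive equations, assembly, simulation.

Architecture (areas 1-5):

* **Area 1** represents the stimulus: two retinotopic ``N x N`` grids, one
  per contrast channel ``F`` (``T1`` = stimulus, ``T2`` = its contrast
  reversal), driven by ``I1F = w1 * TF``.
* **Area 2** performs figure-ground segregation: retinotopic excitation
  ``w2e`` plus global inhibition proportional to the area-1 mean activity,
  ``I2F = w2e*x1F - |w2i|*mean(x1F)``.  The balance of the two terms makes
  the white region spike when it is the smaller region, and makes the
  complementary region fire by rebound (inhibition-driven) when the white
  region is the larger one, so both channels end up highlighting the same
  "figure".
* **Area 3** extracts oriented borders: four two-pixel difference kernels
  applied to the binarized area-2 activity; detections are driven with
  ``w3``.
* **Area 4** holds one cell per channel/subchannel that integrates the
  spatial mean of its area-3 map (``I4Fj = kappa4*w4*mean(x3Fj)``).
* **Area 5** holds the two output cells, ``I5i = sum_Fj w5[i][F][j]*x4Fj``,
  with the learned-weight matrices ``w5`` built from the two constants
  ``A`` (first row, F=1) and ``B < A`` (second row, F=2).

All reductions over grids use a permutation-invariant (sorted) summation so
that runs on mirrored or rotated stimuli reproduce the drive time series
exactly, bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from typing import Optional

import numpy as np

from .izhikevich import GridState, IzhParams, SpikeRaster, izh_step, update_trace
from .stimuli import BinaryImage, contrast_reverse

__all__ = [
    "FilterKernel",
    "NetworkConfig",
    "NetworkRun",
    "DEFAULT_FILTERS",
    "area1_drive",
    "area2_drive",
    "area3_drive",
    "area4_drive",
    "area5_drive",
    "binarize_map",
    "default_w5",
    "feature_map",
    "make_channels",
    "permutation_invariant_mean",
    "run_network",
]


def permutation_invariant_mean(x: np.ndarray) -> float:
    """Mean of ``x`` computed so any permutation of the entries gives the
    bit-identical result (sort before summing)."""
    flat = np.sort(x, axis=None)
    return float(flat.sum()) / flat.size


@dataclasses.dataclass(frozen=True)
class FilterKernel:
    """One of the four two-pixel +-1 border filters.

    ``minus`` and ``plus`` are (row, col) offsets of the -1 and +1
    coefficients relative to the output site.  With binary inputs the
    thresholded correlation detects exactly the sites where the ``plus``
    pixel is white and the ``minus`` pixel is black, i.e. an oriented,
    polarity-specific border.
    """

    index: int
    orientation: str  # "along-row" (vertical borders) or "along-column"
    minus: tuple[int, int]
    plus: tuple[int, int]

    def __post_init__(self) -> None:
        if self.orientation not in ("along-row", "along-column"):
            raise ValueError(f"bad orientation {self.orientation!r}")
        offs = {self.minus, self.plus}
        if len(offs) != 2 or (0, 0) not in offs:
            raise ValueError("kernel must cover the anchor pixel and one neighbour")


# Along-row kernels (vertical-border detectors) sit at even j, along-column
# (horizontal-border detectors) at odd j; the two output cells then read
# vertical contrast from even columns and horizontal contrast from odd ones.
DEFAULT_FILTERS: tuple[FilterKernel, ...] = (
    FilterKernel(1, "along-column", minus=(0, 0), plus=(1, 0)),
    FilterKernel(2, "along-row", minus=(0, 0), plus=(0, 1)),
    FilterKernel(3, "along-column", minus=(1, 0), plus=(0, 0)),
    FilterKernel(4, "along-row", minus=(0, 1), plus=(0, 0)),
)


def default_w5(A: float, B: float) -> np.ndarray:
    """The two learned-weight matrices, shape (2 cells, 2 channels, 4 subchannels).

    Cell 1 reads the even (vertical-contrast) subchannels, cell 2 the odd
    ones; row F=1 carries ``A``, row F=2 the smaller ``B`` — that asymmetry
    is what suppresses figure-ground-reversed displays, whose strongest
    signal arrives through the F=2 channel.
    """
    if B >= A:
        raise ValueError(f"w5 requires B < A, got A={A}, B={B}")
    w5 = np.zeros((2, 2, 4))
    w5[0, 0, [1, 3]] = A  # cell 1, F=1, even j (j=2,4 -> indices 1,3)
    w5[0, 1, [1, 3]] = B
    w5[1, 0, [0, 2]] = A  # cell 2, F=1, odd j
    w5[1, 1, [0, 2]] = B
    return w5


_RS = IzhParams(0.02, 0.2, -65.0, 8.0)


@dataclasses.dataclass
class NetworkConfig:
    """All constants of the model.

    Drive weights (in the model's current units, uA): ``w1=10, w2e=400,
    w2i=-750, w3=500, w4=5.0, A=100, B=5``, 100 ms simulated at
    ``dt=0.25`` ms.

    The remaining fields are integration plumbing that the drive equations
    leave open, fixed here to realize the intended regimes:

    tau_syn : ms — decay of the spike traces entering areas 3-5.
    tau_syn_input : ms — decay of the area-1 output trace; short, so the
        global inhibition arrives as brief strong pulses whose slow-recovery
        imprint on area-2 cells separates the rebound regime from the
        merely-inhibited one.
    kappa4 : dimensionless area-4 gain; the literal mean-normalized drive
        (w4 over N^2 sites) is far subthreshold for realistic border
        fractions, kappa4 rescales it equally for every subchannel.
    theta_b : binarization threshold (fraction of trace_saturation) for the
        area-2 activity map fed to the border filters.
    area2_bias : uA of tonic hyperpolarizing current to area 2; sets the
        operating point at which the inhibition ladder splits into
        silent/spiking/rebound classes (see docs/methods.md).
    """

    w1: float = 10.0
    w2e: float = 400.0
    w2i: float = -750.0
    w3: float = 500.0
    w4: float = 5.0
    A: float = 100.0
    B: float = 5.0
    dt: float = 0.25
    duration: float = 100.0
    tau_syn: float = 5.0
    tau_syn_input: float = 0.4
    kappa4: float = 250.0
    theta_b: float = 0.4
    trace_saturation: float = 1.0
    area2_bias: float = -17.4
    area1_params: IzhParams = IzhParams(0.02, 0.2, -60.0, 2.0)
    area2_params: IzhParams = IzhParams(0.25, 0.5, -55.0, 0.1)
    area3_params: IzhParams = _RS
    area4_params: IzhParams = _RS
    area5_params: IzhParams = _RS
    v_init: float = -65.0
    jitter_mv: float = 0.0
    jitter_seed: Optional[int] = None
    filters: tuple[FilterKernel, ...] = DEFAULT_FILTERS

    def __post_init__(self) -> None:
        if self.B >= self.A:
            raise ValueError(
                f"B ({self.B}) must be smaller than A ({self.A}); the "
                "FG-suppression mechanism needs the F=2 row weaker"
            )
        if self.w2i > 0:
            raise ValueError(f"w2i is an inhibitory weight and must be <= 0, got {self.w2i}")
        if not 0 < self.theta_b <= 1:
            raise ValueError(f"theta_b must lie in (0, 1], got {self.theta_b}")
        if self.dt <= 0 or self.duration <= 0:
            raise ValueError("dt and duration must be positive")
        n_steps = round(self.duration / self.dt)
        if not math.isclose(n_steps * self.dt, self.duration):
            raise ValueError(f"duration {self.duration} is not a multiple of dt {self.dt}")
        if len(self.filters) != 4:
            raise ValueError("exactly 4 filter kernels required")
        if self.jitter_mv and self.jitter_seed is None:
            raise ValueError("jitter_mv > 0 requires jitter_seed")

    @property
    def n_steps(self) -> int:
        return round(self.duration / self.dt)

    @property
    def w5(self) -> np.ndarray:
        return default_w5(self.A, self.B)

    # -- serialization -----------------------------------------------------

    _AREA_KEYS = ("area1_params", "area2_params", "area3_params", "area4_params", "area5_params")

    def to_dict(self) -> dict:
        d = {}
        for f in dataclasses.fields(self):
            val = getattr(self, f.name)
            if f.name in self._AREA_KEYS:
                d[f.name] = dataclasses.asdict(val)
            elif f.name == "filters":
                d[f.name] = [dataclasses.asdict(k) for k in val]
            else:
                d[f.name] = val
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(d)
        for key in cls._AREA_KEYS:
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = IzhParams(**kwargs[key])
        if "filters" in kwargs:
            kwargs["filters"] = tuple(
                k if isinstance(k, FilterKernel)
                else FilterKernel(**{**k, "minus": tuple(k["minus"]), "plus": tuple(k["plus"])})
                for k in kwargs["filters"]
            )
        return cls(**kwargs)

    def config_hash(self) -> str:
        """Stable hash of the full configuration, recorded in reports."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Drive equations
# ---------------------------------------------------------------------------

def make_channels(img: BinaryImage) -> tuple[BinaryImage, BinaryImage]:
    """The two contrast channels: T1 = stimulus, T2 = its contrast reversal."""
    return img, contrast_reverse(img)


def area1_drive(TF: np.ndarray, w1: float) -> np.ndarray:
    """``I1F = w1 * TF``: retinotopic representation of the (binary) channel."""
    return w1 * TF.astype(np.float64)


def area2_drive(x1: np.ndarray, w2e: float, w2i: float) -> np.ndarray:
    """Retinotopic excitation minus global inhibition.

    ``I2F = w2e*x1 - |w2i|*mean(x1)``; the second term is identical at every
    site and uses the permutation-invariant mean.
    """
    return w2e * x1 - abs(w2i) * permutation_invariant_mean(x1)


def binarize_map(x: np.ndarray, theta_b: float, trace_saturation: float = 1.0) -> np.ndarray:
    """Binary activity map: 1 where the trace reaches ``theta_b * trace_saturation``."""
    return (x >= theta_b * trace_saturation).astype(np.uint8)


def feature_map(S_bin: np.ndarray, kernel: FilterKernel) -> np.ndarray:
    """Thresholded correlation of a binary map with a two-pixel +-1 kernel.

    Output site ``(r, c)`` is 1 exactly when the pixel at the ``plus``
    offset is 1 and the pixel at the ``minus`` offset is 0 (zero padding
    outside the array) — the step function applied to ``S * f - 1``.
    """
    out = np.zeros_like(S_bin, dtype=np.uint8)
    H, W = S_bin.shape
    pad = np.zeros((H + 2, W + 2), dtype=S_bin.dtype)
    pad[1:-1, 1:-1] = S_bin
    pr, pc = kernel.plus
    mr, mc = kernel.minus
    plus = pad[1 + pr : 1 + pr + H, 1 + pc : 1 + pc + W]
    minus = pad[1 + mr : 1 + mr + H, 1 + mc : 1 + mc + W]
    np.logical_and(plus == 1, minus == 0, out=out.view(bool))
    return out


def area3_drive(detections: np.ndarray, w3: float) -> np.ndarray:
    """``I3Fj = w3`` at detection sites, 0 elsewhere."""
    return w3 * detections.astype(np.float64)


def area4_drive(x3: np.ndarray, w4: float, kappa4: float) -> float:
    """``I4Fj = kappa4 * w4 * mean(x3Fj)`` (kappa4=1 is the literal equation)."""
    return kappa4 * w4 * permutation_invariant_mean(x3)


def area5_drive(x4: np.ndarray, w5_i: np.ndarray) -> float:
    """``I5i = sum_F sum_j w5[i][F][j] * x4[F][j]``.

    Summed over a fixed balanced tree so that exchanging the two same-weight
    subchannels within a row (as mirroring or rotating the stimulus does)
    leaves the floating-point result bit-identical.
    """
    t1 = (w5_i[0, 0] * x4[0, 0] + w5_i[0, 1] * x4[0, 1]) + (
        w5_i[0, 2] * x4[0, 2] + w5_i[0, 3] * x4[0, 3]
    )
    t2 = (w5_i[1, 0] * x4[1, 0] + w5_i[1, 1] * x4[1, 1]) + (
        w5_i[1, 2] * x4[1, 2] + w5_i[1, 3] * x4[1, 3]
    )
    return t1 + t2


# ---------------------------------------------------------------------------
# Full network
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class NetworkRun:
    """Rasters and drive logs of one stimulus presentation.

    ``rasters`` keys: ``("area1", F)``, ``("area2", F)`` with F in {1, 2};
    ``("area3", F, j)`` with j in {1..4}; ``"area4"`` (grid shape (2, 4));
    ``"area5"`` (grid shape (2,)).
    """

    stimulus: BinaryImage
    config: NetworkConfig
    rasters: dict
    drive_log: dict

    def area5_trains(self) -> tuple[np.ndarray, np.ndarray]:
        """Spike trains (ms) of output cells 1 and 2."""
        r: SpikeRaster = self.rasters["area5"]
        return r.spike_times((0,)), r.spike_times((1,))


def run_network(img: BinaryImage, config: NetworkConfig) -> NetworkRun:
    """Synchronous simulation of the five areas on one stimulus.

    Each step computes every area's drive from the previous step's filtered
    presynaptic activity (one-step feed-forward delay), then advances all
    areas together by one Euler step and updates the traces.
    """
    N = img.N
    cfg = config
    dt, n_steps = cfg.dt, cfg.n_steps
    T1, T2 = make_channels(img)
    T = [T1.pixels, T2.pixels]

    rng = np.random.default_rng(cfg.jitter_seed) if cfg.jitter_mv else None

    def init(shape, params):
        return GridState.initial(shape, params, v0=cfg.v_init,
                                 jitter_mv=cfg.jitter_mv, rng=rng)

    s1 = [init((N, N), cfg.area1_params) for _ in range(2)]
    s2 = [init((N, N), cfg.area2_params) for _ in range(2)]
    s3 = [[init((N, N), cfg.area3_params) for _ in range(4)] for _ in range(2)]
    s4 = init((2, 4), cfg.area4_params)
    s5 = init((2,), cfg.area5_params)

    spikes = {
        ("area1", 1): np.zeros((n_steps, N, N), dtype=bool),
        ("area1", 2): np.zeros((n_steps, N, N), dtype=bool),
        ("area2", 1): np.zeros((n_steps, N, N), dtype=bool),
        ("area2", 2): np.zeros((n_steps, N, N), dtype=bool),
        "area4": np.zeros((n_steps, 2, 4), dtype=bool),
        "area5": np.zeros((n_steps, 2), dtype=bool),
    }
    for F in (1, 2):
        for j in range(1, 5):
            spikes[("area3", F, j)] = np.zeros((n_steps, N, N), dtype=bool)

    I1 = [area1_drive(T[F], cfg.w1) for F in range(2)]
    w5 = cfg.w5
    i4_log = np.zeros((n_steps, 2, 4))
    i5_log = np.zeros((n_steps, 2))

    for k in range(n_steps):
        # drives from the previous step's traces
        I2 = [area2_drive(s1[F].trace, cfg.w2e, cfg.w2i) + cfg.area2_bias for F in range(2)]
        I3 = []
        for F in range(2):
            S2b = binarize_map(s2[F].trace, cfg.theta_b, cfg.trace_saturation)
            I3.append([area3_drive(feature_map(S2b, kern), cfg.w3) for kern in cfg.filters])
        I4 = np.array(
            [[area4_drive(s3[F][j].trace, cfg.w4, cfg.kappa4) for j in range(4)] for F in range(2)]
        )
        x4 = s4.trace
        I5 = np.array([area5_drive(x4, w5[i]) for i in range(2)])
        i4_log[k] = I4
        i5_log[k] = I5

        # advance all areas one step, then refresh traces
        for F in range(2):
            sp = izh_step(s1[F], I1[F], cfg.area1_params, dt)
            spikes[("area1", F + 1)][k] = sp
            s1[F].trace = update_trace(s1[F].trace, sp, dt, cfg.tau_syn_input)

            sp = izh_step(s2[F], I2[F], cfg.area2_params, dt)
            spikes[("area2", F + 1)][k] = sp
            s2[F].trace = update_trace(s2[F].trace, sp, dt, cfg.tau_syn)

            for j in range(4):
                sp = izh_step(s3[F][j], I3[F][j], cfg.area3_params, dt)
                spikes[("area3", F + 1, j + 1)][k] = sp
                s3[F][j].trace = update_trace(s3[F][j].trace, sp, dt, cfg.tau_syn)

        sp = izh_step(s4, I4, cfg.area4_params, dt)
        spikes["area4"][k] = sp
        s4.trace = update_trace(s4.trace, sp, dt, cfg.tau_syn)

        sp = izh_step(s5, I5, cfg.area5_params, dt)
        spikes["area5"][k] = sp
        s5.trace = update_trace(s5.trace, sp, dt, cfg.tau_syn)

    rasters = {key: SpikeRaster(arr, dt) for key, arr in spikes.items()}
    return NetworkRun(
        stimulus=img,
        config=cfg,
        rasters=rasters,
        drive_log={"I4": i4_log, "I5": i5_log},
    )
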