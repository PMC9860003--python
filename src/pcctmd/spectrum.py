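"""Source spectrum, spectral channelization, and detector response.

The 140 kVp source is a filtered-bremsstrahlung shape (Kramers' law times
exponential aluminum filtration) normalized to a configurable total
fluence per detector cell per view.  Spectral channels are contiguous
integer-keV intervals; the presets used by the packaged experiments
([1-58, 59-140] keV for two channels, etc.) are shipped as named
configurations, and an equal-count channelization algorithm is
provided for arbitrary spectra.

The realistic CZT-like response is a parameterized kernel, not a particle
transport simulation: a Gaussian photopeak, a K-escape satellite at
E - 27 keV, a flat low-energy tail, and charge sharing in which a photon
splits into two recorded counts at u*E and (1-u)*E with u ~ U(0.1, 0.5).
Charge sharing is what couples the channels and produces positive
interchannel count correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .materials import N_BINS, element_mass_attenuation, energy_grid

#: aluminum-equivalent filtration thickness [cm] of the default source,
#: chosen so the two-channel preset boundary (58/59 keV) bisects the
#: detected air-scan counts, per the equal-count channelization goal
DEFAULT_FILTRATION_CM = 0.72
AL_DENSITY = 2.699


@dataclass(frozen=True)
class Spectrum:
    """Expected photons per 1-keV bin per detector cell per view (air scan)."""

    fluence: np.ndarray  # shape (140,)

    def __post_init__(self):
        fl = np.asarray(self.fluence, dtype=float)
        if fl.shape != (N_BINS,):
            raise ValueError("fluence must live on the 140-bin grid")
        if np.any(fl < 0):
            raise ValueError("fluence must be nonnegative")
        object.__setattr__(self, "fluence", fl)

    @property
    def grid(self) -> np.ndarray:
        return energy_grid()

    @property
    def total_fluence(self) -> float:
        return float(self.fluence.sum())


def source_spectrum(kvp: float = 140.0, fluence_scale: float = 1e5,
                    filtration_cm: float = DEFAULT_FILTRATION_CM) -> Spectrum:
    """Filtered 140 kVp bremsstrahlung spectrum.

    Kramers shape (kvp - E)/E multiplied by exp(-mu_Al(E) * t), normalized
    so the summed fluence equals ``fluence_scale``.
    """
    if fluence_scale <= 0:
        raise ValueError("fluence_scale must be positive")
    grid = energy_grid()
    if kvp > grid[-1]:
        raise ValueError("kVp exceeds the energy grid")
    # each 1-keV bin carries the Kramers intensity at its midpoint-below
    # label, so the endpoint bin keeps its half-bin of fluence
    shape = np.clip(kvp - grid + 0.5, 0.0, None) / grid
    mu_al = AL_DENSITY * element_mass_attenuation("Al", grid)
    shape = shape * np.exp(-mu_al * filtration_cm)
    shape[grid > kvp] = 0.0
    return Spectrum(fluence=shape / shape.sum() * fluence_scale)


@dataclass(frozen=True)
class ChannelSet:
    """Contiguous, ordered, non-overlapping integer-keV channels covering [1, 140]."""

    bounds: tuple[tuple[int, int], ...]

    def __post_init__(self):
        b = tuple((int(lo), int(hi)) for lo, hi in self.bounds)
        if b[0][0] != 1 or b[-1][1] != 140:
            raise ValueError("channels must cover [1, 140]")
        for (lo, hi), (lo2, _) in zip(b, b[1:]):
            if lo2 != hi + 1:
                raise ValueError("channels must be contiguous and ordered")
        for lo, hi in b:
            if hi < lo:
                raise ValueError("empty channel")
        object.__setattr__(self, "bounds", b)

    @property
    def n_channels(self) -> int:
        return len(self.bounds)

    def indicator(self, k: int) -> np.ndarray:
        """0/1 mask of grid bins belonging to channel k (0-based)."""
        lo, hi = self.bounds[k]
        grid = energy_grid()
        return ((grid >= lo) & (grid <= hi)).astype(float)

    def channel_of_bins(self) -> np.ndarray:
        """Channel index (0-based) of every grid bin."""
        grid = energy_grid()
        out = np.zeros(N_BINS, dtype=int)
        for k, (lo, hi) in enumerate(self.bounds):
            out[(grid >= lo) & (grid <= hi)] = k
        return out


#: channel presets used by the packaged experiments (keV, inclusive)
CHANNEL_PRESETS: dict[int, ChannelSet] = {
    2: ChannelSet(((1, 58), (59, 140))),
    3: ChannelSet(((1, 51), (52, 68), (69, 140))),
    4: ChannelSet(((1, 43), (44, 58), (59, 72), (73, 140))),
}


def channelize_equal_counts(spectrum: Spectrum, k: int) -> ChannelSet:
    """Split the grid into K channels of approximately equal air-scan counts.

    Deterministic greedy cumulative-sum split: channel j ends at the first
    bin where the cumulative fluence reaches j/K of the total.
    """
    if k < 2:
        raise ValueError("need at least 2 channels")
    if k > int((spectrum.fluence > 0).sum()):
        raise ValueError("more channels than populated bins")
    csum = np.cumsum(spectrum.fluence)
    total = csum[-1]
    bounds = []
    lo = 1
    for j in range(1, k):
        hi = int(np.searchsorted(csum, j * total / k - 1e-12) + 1)
        hi = max(hi, lo)  # never emit an empty channel
        bounds.append((lo, hi))
        lo = hi + 1
    bounds.append((lo, 140))
    return ChannelSet(tuple(bounds))


@dataclass(frozen=True)
class DetectorResponse:
    """Ideal or parameterized-realistic spectral response.

    In ideal mode every photon is recorded at its true energy and
    ``sharing_fraction`` is zero.  In realistic mode the recorded-energy
    kernel mixes a Gaussian photopeak (sigma = sigma_a + sigma_b*sqrt(E)),
    a K-escape peak shifted down by ``escape_shift`` keV, and a flat
    low-energy tail; independently, a photon charge-shares with
    probability ``sharing_fraction``, producing two recorded counts at
    u*E and (1-u)*E, u ~ U(u_lo, u_hi).
    """

    mode: str = "ideal"
    efficiency: np.ndarray | None = None
    sigma_a: float = 1.5
    sigma_b: float = 0.3
    escape_shift: float = 27.0
    w_escape: float = 0.08
    w_tail: float = 0.12
    sharing_fraction: float = 0.1
    u_lo: float = 0.1
    u_hi: float = 0.5
    n_u: int = 64

    def __post_init__(self):
        if self.mode not in ("ideal", "realistic"):
            raise ValueError("mode must be 'ideal' or 'realistic'")
        eta = self.efficiency
        eta = np.ones(N_BINS) if eta is None else np.asarray(eta, dtype=float)
        if eta.shape != (N_BINS,) or np.any((eta < 0) | (eta > 1)):
            raise ValueError("efficiency must be in [0,1] on the grid")
        object.__setattr__(self, "efficiency", eta)
        if self.mode == "ideal":
            object.__setattr__(self, "sharing_fraction", 0.0)

    # -- single-count recorded-energy kernel -------------------------------

    def kernel(self) -> np.ndarray:
        """R[rec, inc]: recorded-energy distribution of a non-shared count.

        Columns sum to 1 (recorded energies are clipped into the grid).
        Ideal mode returns the identity.
        """
        if self.mode == "ideal":
            return np.eye(N_BINS)
        grid = energy_grid()
        rec = grid[:, None]
        inc = grid[None, :]
        sigma = self.sigma_a + self.sigma_b * np.sqrt(inc)
        peak = np.exp(-0.5 * ((rec - inc) / sigma) ** 2)
        peak /= peak.sum(axis=0, keepdims=True)
        esc_center = inc - self.escape_shift
        esc = np.exp(-0.5 * ((rec - esc_center) / sigma) ** 2)
        esc_mass = esc.sum(axis=0, keepdims=True)
        has_escape = (esc_center >= 1.0) & (esc_mass > 1e-12)
        esc = np.where(has_escape, esc / np.where(esc_mass == 0, 1, esc_mass), 0.0)
        tail = (rec <= inc).astype(float)
        tail /= tail.sum(axis=0, keepdims=True)
        # fold the escape weight back into the photopeak below the escape
        # threshold so every column still sums to 1
        w_esc = np.where(has_escape[0], self.w_escape, 0.0)[None, :]
        w_pp = 1.0 - w_esc - self.w_tail
        return w_pp * peak + w_esc * esc + self.w_tail * tail

    def split_energy_bins(self, e_inc_bin: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Recorded bin indices of the two counts of a shared photon, for
        every u on the quadrature grid.  Shapes (n_u, len(e_inc_bin))."""
        u = self._u_grid()[:, None]
        e = energy_grid()[e_inc_bin][None, :]
        b1 = np.clip(np.rint(u * e), 1, 140).astype(int) - 1
        b2 = np.clip(np.rint((1 - u) * e), 1, 140).astype(int) - 1
        return b1, b2

    def _u_grid(self) -> np.ndarray:
        step = (self.u_hi - self.u_lo) / self.n_u
        return self.u_lo + step * (np.arange(self.n_u) + 0.5)

    def split_pair_probs(self, channels: ChannelSet) -> np.ndarray:
        """q[E, a, b]: probability that a shared photon of incident energy E
        deposits its two counts in channels (a, b) (ordered pair)."""
        k = channels.n_channels
        chan = channels.channel_of_bins()
        b1, b2 = self.split_energy_bins(np.arange(N_BINS))
        c1, c2 = chan[b1], chan[b2]  # (n_u, nE)
        q = np.zeros((N_BINS, k, k))
        for a in range(k):
            for b in range(k):
                q[:, a, b] = ((c1 == a) & (c2 == b)).mean(axis=0)
        return q

    # -- channel weighting --------------------------------------------------

    def channel_mass(self, channels: ChannelSet) -> np.ndarray:
        """M[E, k]: expected recorded counts in channel k per incident
        photon of energy E (includes the double count of charge sharing)."""
        k = channels.n_channels
        kern = self.kernel()
        chan = channels.channel_of_bins()
        single = np.zeros((N_BINS, k))
        for c in range(k):
            single[:, c] = kern[chan == c, :].sum(axis=0)
        p = self.sharing_fraction
        m = (1.0 - p) * single
        if p > 0:
            q = self.split_pair_probs(channels)
            m = m + p * (q.sum(axis=2) + q.sum(axis=1))
        return self.efficiency[:, None] * m


def channel_weighting(channels: ChannelSet, response: DetectorResponse, k: int) -> np.ndarray:
    """D_k(E) on the grid: detection weight of channel k (0-based index)."""
    if not 0 <= k < channels.n_channels:
        raise IndexError("channel index out of range")
    if response.mode == "ideal":
        return response.efficiency * channels.indicator(k)
    return response.channel_mass(channels)[:, k]


def air_channel_counts(spectrum: Spectrum, channels: ChannelSet,
                       response: DetectorResponse) -> np.ndarray:
    """Expected air-scan counts per channel."""
    return spectrum.fluence @ response.channel_mass(channels)
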