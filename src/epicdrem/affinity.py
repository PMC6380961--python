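"""TRAP-style biophysical TF binding affinities over genomic regions.

The model treats every sequence window of motif length as a potential
binding site. A window's mismatch energy is the sum over motif positions of
the natural-log ratio between the best base's probability and the observed
base's probability; the expected occupancy of the window is the
Fermi-Dirac-like term

    R0 * exp(-E/lambda) / (1 + R0 * exp(-E/lambda))

and the affinity of a region is the sum of window occupancies over both
strands. There is no hard motif cutoff: weak sites contribute small but
non-zero occupancy, which is what distinguishes this score from hit-count
scanners. Defaults follow the published parameterization of the occupancy
model: lambda = 0.7 and ln R0 = 0.584 * motif_length - 5.66.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genomic_io import PWM, GenomicRegion, fetch_sequence

__all__ = [
    "TrapParameters",
    "trap_affinity",
    "score_footprints",
    "FootprintAffinityMatrix",
]

_ENCODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_COMPLEMENT = np.array([3, 2, 1, 0], dtype=np.int8)  # A<->T, C<->G


@dataclass(frozen=True)
class TrapParameters:
    """Occupancy-model constants; ``ln_r0`` of None selects the motif-length
    scaling ``0.584 * L - 5.66``."""

    lambda_: float = 0.7
    ln_r0: float | None = None

    def ln_r0_for(self, motif_length: int) -> float:
        if self.ln_r0 is not None:
            return self.ln_r0
        return 0.584 * motif_length - 5.66


def _encode(sequence: str) -> np.ndarray:
    arr = _ENCODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]
    bad = (arr == -1) & (
        np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8) != ord("N")
    )
    if bad.any():
        pos = int(np.flatnonzero(bad)[0])
        raise ValueError(f"invalid base {sequence[pos]!r} at position {pos}")
    return arr


def _energy_matrix(pwm: PWM) -> np.ndarray:
    """Per (base, position) mismatch energy ln(p_max / p_base); 0 for the
    consensus base at each position."""
    probs = pwm.matrix  # L x 4
    return np.log(probs.max(axis=1, keepdims=True) / probs).T  # 4 x L


def _window_occupancies(
    encoded: np.ndarray, energy: np.ndarray, lambda_: float, ln_r0: float
) -> np.ndarray:
    """Occupancy of each forward-strand window of an encoded sequence.

    Windows containing an N (encoded -1) contribute exactly 0.
    """
    L = energy.shape[1]
    n_pos = encoded.size - L + 1
    if n_pos <= 0:
        return np.zeros(0)
    windows = np.lib.stride_tricks.sliding_window_view(encoded, L)
    valid = (windows >= 0).all(axis=1)
    occ = np.zeros(n_pos)
    if valid.any():
        w = windows[valid]
        e = energy[w, np.arange(L)].sum(axis=1)
        x = np.exp(ln_r0 - e / lambda_)
        occ[valid] = x / (1.0 + x)
    return occ


def trap_affinity(
    pwm: PWM,
    sequence: str,
    lambda_: float = 0.7,
    ln_r0: float | None = None,
    both_strands: bool = True,
) -> float:
    """Expected total occupancy of ``pwm``'s TF on ``sequence``.

    Parameters
    ----------
    pwm:
        Position weight matrix (probabilities, pseudocount already applied).
    sequence:
        DNA over A/C/G/T/N, any case. Must be at least motif length long.
    lambda_:
        Energy scale; must be positive.
    ln_r0:
        Log of the occupancy prefactor R0; defaults to the motif-length
        scaling ``0.584 * L - 5.66``.
    both_strands:
        Also scan the reverse complement and sum occupancies (default).
    """
    if lambda_ <= 0:
        raise ValueError(f"lambda_ must be positive, got {lambda_}")
    L = pwm.motif_length
    if len(sequence) < L:
        raise ValueError(
            f"sequence length {len(sequence)} shorter than motif length {L}"
        )
    params = TrapParameters(lambda_, ln_r0)
    encoded = _encode(sequence)
    energy = _energy_matrix(pwm)
    r0 = params.ln_r0_for(L)
    total = _window_occupancies(encoded, energy, lambda_, r0).sum()
    if both_strands:
        rc = _COMPLEMENT[encoded[::-1].clip(min=0)]
        rc[encoded[::-1] < 0] = -1
        total += _window_occupancies(rc, energy, lambda_, r0).sum()
    return float(total)


@dataclass
class FootprintAffinityMatrix:
    """Regions x TFs affinity matrix for one time point.

    ``raw`` holds summed window occupancies per region; ``normalized``
    divides each region's affinities by that region's own length, putting
    footprints of different widths on a common per-bp scale.
    """

    regions: list[GenomicRegion]
    tfs: list[str]
    raw: np.ndarray
    normalized: np.ndarray
    time_point: str | None = None

    def __post_init__(self) -> None:
        self.raw = np.asarray(self.raw, dtype=float)
        self.normalized = np.asarray(self.normalized, dtype=float)
        shape = (len(self.regions), len(self.tfs))
        if self.raw.shape != shape or self.normalized.shape != shape:
            raise ValueError("affinity matrix shape mismatch")
        if (self.raw < 0).any():
            raise ValueError("negative raw affinity")

    def tf_column(self, tf_name: str, normalized: bool = True) -> np.ndarray:
        j = self.tfs.index(tf_name)
        return (self.normalized if normalized else self.raw)[:, j]


def score_footprints(
    pwms: list[PWM],
    regions: list[GenomicRegion],
    genome: dict[str, str],
    params: TrapParameters = TrapParameters(),
    both_strands: bool = True,
    time_point: str | None = None,
) -> FootprintAffinityMatrix:
    """Score every region against every PWM.

    Regions shorter than a motif get affinity 0 for that motif (no window
    fits) rather than an error, so heterogeneous footprint widths are safe.
    """
    energies = [_energy_matrix(p) for p in pwms]
    raw = np.zeros((len(regions), len(pwms)))
    for i, region in enumerate(regions):
        try:
            seq = fetch_sequence(genome, region)
        except (KeyError, ValueError) as exc:
            raise ValueError(f"cannot score region {region}: {exc}") from exc
        encoded = _encode(seq)
        rc = _COMPLEMENT[encoded[::-1].clip(min=0)]
        rc[encoded[::-1] < 0] = -1
        for j, pwm in enumerate(pwms):
            L = pwm.motif_length
            if len(seq) < L:
                continue
            r0 = params.ln_r0_for(L)
            total = _window_occupancies(encoded, energies[j], params.lambda_, r0).sum()
            if both_strands:
                total += _window_occupancies(rc, energies[j], params.lambda_, r0).sum()
            raw[i, j] = total
    lengths = np.array([r.length for r in regions], dtype=float)
    normalized = raw / lengths[:, None] if len(regions) else raw.copy()
    return FootprintAffinityMatrix(
        regions=list(regions),
        tfs=[p.tf_name for p in pwms],
        raw=raw,
        normalized=normalized,
        time_point=time_point,
    )
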