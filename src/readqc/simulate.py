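"""Deterministic synthetic read generation with platform-profiled length
and quality structure.

Profiles emulate the broad length/quality shapes of common platforms:

``hifi``
    Unimodal lognormal lengths with the mode at ~20 kb and low spread;
    per-read mean quality ~Q30 within the Q20-Q40 window, mildly
    anticorrelated with length (fewer consensus passes on longer reads).
``ont_ul``
    Dispersed bimodal lengths with peaks near 500 bp and 40 kb; low,
    bimodal quality centred near Q7 and Q17.
``illumina``
    Constant 150 bp reads; high quality with the mode at Q39.
``clr``
    Long-tailed lengths in the 10-50 kb range; low single-pass quality
    around Q9.

Distribution families (lognormal lengths, two-component lognormal
mixtures, truncated normal qualities) are this package's modelling
choices; see docs/methods.md.  The same seed always yields byte-identical
files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Tuple, Union

import numpy as np

from .errors import ConfigurationError
from .metrics import MAX_QUALITY, ReadSummary
from .records import FormatTag, ReadRecord

PathLike = Union[str, Path]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class LengthModel:
    """Mixture of lognormals (one component = plain lognormal); constant
    when sigma == 0."""

    modes: Tuple[float, ...]  # length mode of each component, bp
    sigmas: Tuple[float, ...]  # lognormal sigma per component
    weights: Tuple[float, ...]
    min_length: int = 1

    def sample(self, n: int, rng: np.random.Generator) -> Tuple[np.ndarray, np.ndarray]:
        """Returns (lengths, z) where z is the within-component z-score used
        for optional length-quality coupling."""
        comp = rng.choice(len(self.weights), size=n, p=self.weights)
        z = rng.standard_normal(n)
        mu = np.log(np.asarray(self.modes))[comp]
        sig = np.asarray(self.sigmas)[comp]
        # mode of lognormal(mu', sigma) is exp(mu' - sigma^2): shift so the
        # requested mode is the actual density peak
        lengths = np.exp(mu + sig**2 + sig * z)
        lengths = np.maximum(np.rint(lengths).astype(np.int64), self.min_length)
        return lengths, z


@dataclass(frozen=True)
class QualityModel:
    """Truncated-normal mixture over per-read mean Q."""

    means: Tuple[float, ...]
    sds: Tuple[float, ...]
    weights: Tuple[float, ...]
    q_min: float = 0.0
    q_max: float = float(MAX_QUALITY)
    per_base_sd: float = 2.0
    #: True emulates platform Q capping: out-of-window draws are clamped,
    #: piling probability mass at the cap (the Illumina/Revio "mode at the
    #: cap" shape).  False truncates by rejection instead.
    cap_style: bool = False

    def sample_read_means(
        self, n: int, rng: np.random.Generator, z_len: Optional[np.ndarray] = None,
        length_coupling: float = 0.0,
    ) -> np.ndarray:
        comp = rng.choice(len(self.weights), size=n, p=self.weights)
        mu = np.asarray(self.means)[comp]
        sd = np.asarray(self.sds)[comp]
        if z_len is not None and length_coupling:
            mu = mu - length_coupling * z_len
        q = mu + sd * rng.standard_normal(n)
        if not self.cap_style:
            # resample out-of-window draws (simple rejection, vectorised)
            for _ in range(64):
                bad = (q < self.q_min) | (q > self.q_max)
                if not bad.any():
                    break
                q[bad] = mu[bad] + sd[bad] * rng.standard_normal(int(bad.sum()))
        return np.clip(q, self.q_min, self.q_max)


@dataclass(frozen=True)
class PlatformProfile:
    name: str
    lengths: LengthModel
    quality: Optional[QualityModel]  # None = no quality strings (FASTA-like)
    #: Phred units of mean-Q shift per length z-score (positive values make
    #: longer reads lower quality).
    length_quality_coupling: float = 0.0
    #: probability that a base repeats its predecessor (homopolymer
    #: enrichment; 0.25 would be like uniform i.i.d. draws)
    repeat_prob: float = 0.0


PROFILES = {
    "hifi": PlatformProfile(
        name="hifi",
        lengths=LengthModel(modes=(20_000.0,), sigmas=(0.13,), weights=(1.0,)),
        quality=QualityModel(
            means=(30.0,), sds=(3.0,), weights=(1.0,), q_min=20.0, q_max=40.0
        ),
        length_quality_coupling=2.5,
    ),
    "ont_ul": PlatformProfile(
        name="ont_ul",
        lengths=LengthModel(
            modes=(500.0, 40_000.0), sigmas=(0.45, 0.35), weights=(0.5, 0.5)
        ),
        quality=QualityModel(
            means=(7.0, 17.0), sds=(1.3, 1.3), weights=(0.55, 0.45),
            q_min=1.0, q_max=30.0,
        ),
    ),
    "illumina": PlatformProfile(
        name="illumina",
        lengths=LengthModel(modes=(150.0,), sigmas=(0.0,), weights=(1.0,)),
        quality=QualityModel(
            means=(39.0,), sds=(4.0,), weights=(1.0,),
            q_min=2.0, q_max=39.0, cap_style=True,
        ),
    ),
    "clr": PlatformProfile(
        name="clr",
        lengths=LengthModel(modes=(15_000.0,), sigmas=(0.55,), weights=(1.0,)),
        quality=QualityModel(
            means=(9.0,), sds=(1.5,), weights=(1.0,), q_min=4.0, q_max=14.0
        ),
    ),
}


def get_profile(name: str) -> PlatformProfile:
    try:
        return PROFILES[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown platform profile {name!r} (choose from {sorted(PROFILES)})"
        ) from None


def sample_length_quality(
    profile: PlatformProfile, n: int, rng: np.random.Generator
) -> Tuple[np.ndarray, Optional[np.ndarray]]:
    """Draw n (length, per-read mean Q) pairs from the profile."""
    lengths, z = profile.lengths.sample(n, rng)
    qmeans = None
    if profile.quality is not None:
        qmeans = profile.quality.sample_read_means(
            n, rng, z_len=z, length_coupling=profile.length_quality_coupling
        )
    return lengths, qmeans


def _random_sequence(length: int, rng: np.random.Generator, repeat_prob: float) -> str:
    draws = _BASES[rng.integers(0, 4, size=length)]
    if repeat_prob <= 0.0 or length < 2:
        return draws.tobytes().decode("latin-1")
    # Markov repeat structure without a per-base Python loop: positions that
    # "innovate" keep their draw, the rest copy forward the last innovation.
    innovate = rng.random(length) >= repeat_prob
    innovate[0] = True
    idx = np.where(innovate, np.arange(length), 0)
    np.maximum.accumulate(idx, out=idx)
    return draws[idx].tobytes().decode("latin-1")


def _quality_string(
    length: int, qmean: float, per_base_sd: float, rng: np.random.Generator
) -> str:
    q = np.rint(qmean + per_base_sd * rng.standard_normal(length))
    q = np.clip(q, 0, MAX_QUALITY).astype(np.uint8) + 33
    return q.tobytes().decode("latin-1")


def generate_records(
    profile: Union[PlatformProfile, str],
    n: int,
    seed: int,
    name_prefix: str = "read",
) -> Iterator[ReadRecord]:
    """Yield n deterministic synthetic reads from a platform profile."""
    if isinstance(profile, str):
        profile = get_profile(profile)
    if n < 0:
        raise ConfigurationError("read count must be >= 0")
    rng = np.random.default_rng(seed)
    lengths, qmeans = sample_length_quality(profile, n, rng)
    for i in range(n):
        length = int(lengths[i])
        seq = _random_sequence(length, rng, profile.repeat_prob)
        qual = None
        if qmeans is not None:
            qual = _quality_string(
                length, float(qmeans[i]), profile.quality.per_base_sd, rng
            )
        yield ReadRecord(name=f"{name_prefix}{i + 1}", sequence=seq, quality=qual)


def generate_summaries(
    profile: Union[PlatformProfile, str], n: int, seed: int
) -> Iterator[ReadSummary]:
    """Per-read summaries drawn from the profile without materialising
    sequences — the cheap path for distribution-level experiments where
    only (length, quality, composition) matter."""
    if isinstance(profile, str):
        profile = get_profile(profile)
    rng = np.random.default_rng(seed)
    lengths, qmeans = sample_length_quality(profile, n, rng)
    probs = np.full(4, 0.25)
    for i in range(n):
        length = int(lengths[i])
        counts = np.zeros(6, dtype=np.int64)
        counts[:4] = rng.multinomial(length, probs)
        yield ReadSummary(
            length=length,
            base_counts=counts,
            mean_q=None if qmeans is None else float(qmeans[i]),
        )


def simulate_reads(
    profile: Union[PlatformProfile, str],
    n: int,
    seed: int,
    out: PathLike,
    fmt: Union[FormatTag, str, None] = None,
) -> int:
    """Generate n reads and write them to ``out`` (format inferred from the
    extension unless given).  Returns the number of reads written."""
    from . import formats  # local import: avoid cycle at module load

    return formats.write_reads(generate_records(profile, n, seed), out, fmt)
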