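"""Synthetic score tables with known ground truth.

The generator emulates the statistical structure of an engine's filtered
precursor report: a table of targets and decoys (1:1) with a dense sub-score
matrix. Targets are a mixture — a fraction ``pi_true`` are genuine
("detectable") peptides whose informative sub-scores are shifted upward; the
rest are null. A configurable fraction of the null-like target population is
flagged as *entrapment* (the role a foreign proteome, e.g. Arabidopsis among
human targets, plays in real benchmarks), and decoys are drawn from the same
null. Because entrapment rows and false targets share the null distribution
exactly, the entrapment FDR is an unbiased estimate of ``entrap_frac`` times
the false-discovery proportion among accepted targets — i.e. a lower bound,
as in real entrapment experiments.

Null feature vectors are equicorrelated Gaussians (pairwise correlation
``feature_correlation``), generated by a one-factor construction; a
Student-t option (``tail_df``) provides heavier tails for robustness checks.
True targets add ``effect_size`` (in null-sd units) to the first
``n_informative`` coordinates.

Presets mimic the scale and signal regimes of common dataset types: large
high-signal QC runs down to small low-signal single-cell runs, the regime
most prone to discriminator overfitting.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Any, Mapping

import numpy as np

from .decoys import generate_decoy
from .exceptions import ConfigError
from .table import ScoreTable

AA20 = "GAVLIFMPWSCTYHKRQEND"


@dataclass
class SyntheticConfig:
    """Generator parameters.

    n_targets : number of target rows (decoys are generated 1:1).
    pi_true : fraction of targets that are genuine (Bernoulli per target).
    entrap_frac : fraction of the *false* target population flagged as
        entrapment species. Default 0.45, the ratio of a typical entrapment
        library to a human target library.
    n_features / n_informative : sub-score count and how many carry signal.
    effect_size : mean shift of true targets on informative features, in
        null standard deviations.
    feature_correlation : equicorrelation rho in [0, 1) among features.
    tail_df : degrees of freedom for Student-t nulls (None = Gaussian);
        draws are rescaled to unit variance so effect_size keeps its units.
    with_sequences : also generate random tryptic-length peptide sequences
        for targets and their mutation decoys.
    """

    n_targets: int = 2000
    pi_true: float = 0.15
    entrap_frac: float = 0.45
    n_features: int = 50
    n_informative: int = 10
    effect_size: float = 3.0
    feature_correlation: float = 0.2
    tail_df: int | None = None
    with_sequences: bool = True
    length_range: tuple[int, int] = (7, 30)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_targets < 1:
            raise ConfigError("n_targets must be >= 1")
        if not 0.0 <= self.pi_true <= 1.0:
            raise ConfigError("pi_true must be in [0, 1]")
        if not 0.0 <= self.entrap_frac <= 1.0:
            raise ConfigError("entrap_frac must be in [0, 1]")
        if self.n_informative > self.n_features:
            raise ConfigError("n_informative cannot exceed n_features")
        if not 0.0 <= self.feature_correlation < 1.0:
            raise ConfigError("feature_correlation must be in [0, 1)")
        if self.tail_df is not None and self.tail_df <= 2:
            raise ConfigError("tail_df must be > 2 (finite variance)")
        if self.pi_true > 0 and self.effect_size > 0 and self.n_informative == 0:
            raise ConfigError(
                "pi_true > 0 with effect_size > 0 needs n_informative >= 1"
            )

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["length_range"] = list(self.length_range)
        return d

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "SyntheticConfig":
        d = dict(d)
        if "length_range" in d:
            d["length_range"] = tuple(d["length_range"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Hidden truth: which rows are genuine targets.

    Enables exact false-discovery-proportion computation, the role the
    entrapment species plays in real benchmarks.
    """

    is_true_target: np.ndarray = field(default_factory=lambda: np.empty(0, bool))

    def fdp(self, accepted: np.ndarray) -> float:
        """Exact FDP of an accepted row set (mask or indices); 0 if empty."""
        accepted = np.asarray(accepted)
        idx = np.flatnonzero(accepted) if accepted.dtype == bool else accepted
        if idx.size == 0:
            return 0.0
        return float((~self.is_true_target[idx]).sum()) / idx.size


def _null_draws(rng: np.random.Generator, shape, df: int | None) -> np.ndarray:
    if df is None:
        return rng.standard_normal(shape)
    return rng.standard_t(df, size=shape) / np.sqrt(df / (df - 2))


def generate_table(config: SyntheticConfig) -> tuple[ScoreTable, GroundTruth]:
    """Draw one synthetic score table plus its ground truth.

    Fully deterministic given ``config.seed``: the same config yields a
    byte-identical table.
    """
    rng = np.random.default_rng(config.seed)
    nt = config.n_targets
    n = 2 * nt  # decoys 1:1
    p = config.n_features
    rho = config.feature_correlation

    is_target = np.zeros(n, dtype=bool)
    is_target[:nt] = True
    is_true = np.zeros(n, dtype=bool)
    is_true[:nt] = rng.random(nt) < config.pi_true
    entrapment = np.zeros(n, dtype=bool)
    false_targets = np.flatnonzero(is_target & ~is_true)
    entrapment[false_targets] = rng.random(false_targets.size) < config.entrap_frac

    # one-factor equicorrelated nulls: x = sqrt(rho) g + sqrt(1-rho) e
    g = _null_draws(rng, (n, 1), config.tail_df)
    e = _null_draws(rng, (n, p), config.tail_df)
    scores = np.sqrt(rho) * g + np.sqrt(1.0 - rho) * e
    scores[is_true, : config.n_informative] += config.effect_size

    ids = np.array(
        [f"{'T' if is_target[i] else 'D'}{i:07d}" for i in range(n)], dtype=object
    )
    sequences = None
    if config.with_sequences:
        pep = generate_peptides(
            nt, length_range=config.length_range, seed=int(rng.integers(2**31))
        )
        sequences = np.array(pep + [generate_decoy(s) for s in pep], dtype=object)

    table = ScoreTable(
        ids=ids,
        is_target=is_target,
        entrapment=entrapment,
        scores=scores,
        feature_names=[f"score_{j:03d}" for j in range(p)],
        sequences=sequences,
    )
    return table, GroundTruth(is_true_target=is_true)


#: scale/signal regimes of common dataset types
_PRESETS: dict[str, dict[str, Any]] = {
    "qc_like": {"n_targets": 20000, "pi_true": 0.60},
    "highthroughput_like": {"n_targets": 10000, "pi_true": 0.40},
    "plasma_like": {"n_targets": 3000, "pi_true": 0.20},
    "singlecell_like": {"n_targets": 2000, "pi_true": 0.15},
}

PRESET_NAMES = tuple(_PRESETS)


def dataset_presets(name: str, seed: int = 0, **overrides: Any) -> SyntheticConfig:
    """A named preset config; overrides are applied on top."""
    if name not in _PRESETS:
        raise ConfigError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    kwargs: dict[str, Any] = dict(_PRESETS[name])
    kwargs.update(overrides)
    return SyntheticConfig(seed=seed, **kwargs)


def generate_peptides(
    n: int, length_range: tuple[int, int] = (7, 30), seed: int = 0
) -> list[str]:
    """Uniform-random peptides over the 20 letters within ``length_range``."""
    lo, hi = length_range
    if lo > hi or lo < 1:
        raise ConfigError(f"invalid length range {length_range}")
    if n < 0:
        raise ConfigError("n must be >= 0")
    rng = np.random.default_rng(seed)
    letters = np.array(list(AA20))
    lengths = rng.integers(lo, hi + 1, size=n)
    return ["".join(rng.choice(letters, size=int(L))) for L in lengths]
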