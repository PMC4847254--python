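"""Core/pan-genome rarefaction and exponential-law fitting.

For each subset size ``n`` the sampler draws ``n_samples`` random strain
subsets (uniformly, without replacement within a subset) from the
strain x cluster presence matrix and records

* ``pan(n)``  — clusters present in at least one subset member, and
* ``core(n)`` — clusters present in at least ``ceil(core_fraction * n)``
  subset members (the same >=75% ceiling rule as the global core
  definition; a strict 100% core is available by flag).

Medians are *lower medians* (the lower central order statistic), so all
reported medians are integers and exhaustive-enumeration comparisons are
exact.  The per-size median curves are then fitted with the three-
parameter exponential law ``f(n) = A * exp(-n / B) + C``; the pan-genome
is called *open* when the fitted curve still gains more than a threshold
number of new genes per additional genome at the full collection size.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "RarefactionResult", "ExactCurves", "ExpFit", "OpennessCall",
    "sample_curves", "exhaustive_curves", "fit_exponential",
    "openness_call", "clade_exclusion_rerun",
]


def _as_matrix(presence) -> tuple[list[str], np.ndarray]:
    if isinstance(presence, pd.DataFrame):
        return list(presence.index), presence.to_numpy(dtype=bool)
    arr = np.asarray(presence, dtype=bool)
    return [f"strain_{i + 1:03d}" for i in range(arr.shape[0])], arr


def _core_need(n: int, core_fraction: float, strict: bool) -> int:
    if strict:
        return n
    return math.ceil(core_fraction * n - 1e-9)


def lower_median(values: np.ndarray) -> int:
    """Lower central order statistic; integer for integer inputs."""
    v = np.sort(np.asarray(values))
    return int(v[(len(v) - 1) // 2])


@dataclass
class RarefactionResult:
    sizes: list[int]
    core_samples: dict[int, np.ndarray]
    pan_samples: dict[int, np.ndarray]
    median_core: list[int]
    median_pan: list[int]
    n_samples: int
    seed: int
    core_fraction: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"n": self.sizes,
                             "median_core": self.median_core,
                             "median_pan": self.median_pan})


@dataclass
class ExactCurves:
    sizes: list[int]
    median_core: list[int]          # lower medians
    median_pan: list[int]
    median_core_upper: list[int]    # upper medians (tie partners)
    median_pan_upper: list[int]


def _sample_at(mat: np.ndarray, n: int, n_samples: int, rng,
               core_fraction: float, strict: bool
               ) -> tuple[np.ndarray, np.ndarray]:
    n_strains = mat.shape[0]
    # uniform subsets of size n: first n of a random permutation per draw
    order = np.argsort(rng.random((n_samples, n_strains)), axis=1)[:, :n]
    counts = mat[order].sum(axis=1)            # n_samples x clusters
    pan = (counts >= 1).sum(axis=1)
    core = (counts >= _core_need(n, core_fraction, strict)).sum(axis=1)
    return core.astype(np.int64), pan.astype(np.int64)


def sample_curves(presence, n_samples: int, seed: int,
                  core_fraction: float = 0.75,
                  strict_core: bool = False) -> RarefactionResult:
    """Monte-Carlo rarefaction curves over all subset sizes 1..N."""
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    labels, mat = _as_matrix(presence)
    if mat.size == 0:
        raise ValueError("presence matrix is empty")
    N = mat.shape[0]
    rng = np.random.default_rng(seed)
    sizes = list(range(1, N + 1))
    core_samples, pan_samples, med_core, med_pan = {}, {}, [], []
    for n in sizes:
        core, pan = _sample_at(mat, n, n_samples, rng, core_fraction,
                               strict_core)
        core_samples[n], pan_samples[n] = core, pan
        med_core.append(lower_median(core))
        med_pan.append(lower_median(pan))
    return RarefactionResult(sizes=sizes, core_samples=core_samples,
                             pan_samples=pan_samples, median_core=med_core,
                             median_pan=med_pan, n_samples=n_samples,
                             seed=seed, core_fraction=core_fraction)


def exhaustive_curves(presence, core_fraction: float = 0.75,
                      strict_core: bool = False,
                      max_strains: int = 12) -> ExactCurves:
    """Exact per-size medians by enumerating every strain subset."""
    labels, mat = _as_matrix(presence)
    N = mat.shape[0]
    if N > max_strains:
        raise ValueError(
            f"{N} strains exceeds the enumeration guard ({max_strains}); "
            f"use sample_curves for larger collections")
    sizes = list(range(1, N + 1))
    mc, mp, mcu, mpu = [], [], [], []
    for n in sizes:
        cores, pans = [], []
        need = _core_need(n, core_fraction, strict_core)
        for subset in itertools.combinations(range(N), n):
            counts = mat[list(subset)].sum(axis=0)
            pans.append(int((counts >= 1).sum()))
            cores.append(int((counts >= need).sum()))
        cores.sort()
        pans.sort()
        m = len(cores)
        mc.append(cores[(m - 1) // 2])
        mp.append(pans[(m - 1) // 2])
        mcu.append(cores[m // 2])
        mpu.append(pans[m // 2])
    return ExactCurves(sizes=sizes, median_core=mc, median_pan=mp,
                       median_core_upper=mcu, median_pan_upper=mpu)


# ---------------------------------------------------------------- fitting

@dataclass
class ExpFit:
    A: float
    B: float            # decay constant, in genomes; > 0
    C: float            # asymptote, in genes
    rss: float
    converged: bool

    def predict(self, n) -> np.ndarray:
        n = np.asarray(n, dtype=float)
        return self.A * np.exp(-n / self.B) + self.C


def _exp_model(n, A, B, C):
    return A * np.exp(-n / B) + C


def fit_exponential(medians) -> ExpFit:
    """Least-squares fit of ``A*exp(-n/B) + C`` with multi-start B."""
    y = np.asarray(medians, dtype=float)
    if len(y) < 4:
        raise ValueError("need at least 4 points to fit")
    n = np.arange(1, len(y) + 1, dtype=float)
    if np.allclose(y, y[0]):
        return ExpFit(A=0.0, B=1.0, C=float(y.mean()), rss=0.0,
                      converged=True)
    best = None
    span = float(y[0] - y[-1])
    for b0 in (1.0, 2.0, 5.0, 10.0, 25.0, 50.0, len(y) / 2.0, float(len(y))):
        try:
            popt, _ = curve_fit(
                _exp_model, n, y, p0=[span if span != 0 else 1.0, b0,
                                      float(y[-1])],
                bounds=([-np.inf, 1e-9, -np.inf], [np.inf, np.inf, np.inf]),
                maxfev=20000)
        except (RuntimeError, ValueError):
            continue
        rss = float(((y - _exp_model(n, *popt)) ** 2).sum())
        if best is None or rss < best[1]:
            best = (popt, rss)
    if best is None:
        return ExpFit(A=0.0, B=1.0, C=float(y.mean()),
                      rss=float(((y - y.mean()) ** 2).sum()), converged=False)
    (A, B, C), rss = best
    return ExpFit(A=float(A), B=float(B), C=float(C), rss=rss,
                  converged=True)


@dataclass
class OpennessCall:
    status: str                 # open / closed / indeterminate
    rate_at_N: float            # new genes per additional genome at n = N
    threshold: float


def openness_call(fit_pan: ExpFit, N: int,
                  threshold: float = 1.0) -> OpennessCall:
    """Open/closed pan-genome decision from the fitted curve's slope.

    The per-genome gain at the full collection size is
    ``f'(N) = -(A/B) * exp(-N/B)``; the pan-genome is *open* when this
    still exceeds ``threshold`` genes per genome.
    """
    if not fit_pan.converged:
        return OpennessCall(status="indeterminate", rate_at_N=float("nan"),
                            threshold=threshold)
    rate = -(fit_pan.A / fit_pan.B) * math.exp(-N / fit_pan.B)
    status = "open" if rate > threshold else "closed"
    return OpennessCall(status=status, rate_at_N=rate, threshold=threshold)


# ------------------------------------------------------- clade exclusion

@dataclass
class PairedRarefaction:
    subset_size: int
    full_core: int
    full_pan: int
    reduced_core: int
    reduced_pan: int
    full_core_samples: np.ndarray = field(repr=False, default=None)
    full_pan_samples: np.ndarray = field(repr=False, default=None)
    reduced_core_samples: np.ndarray = field(repr=False, default=None)
    reduced_pan_samples: np.ndarray = field(repr=False, default=None)


def clade_exclusion_rerun(presence, exclude, n_samples: int,
                          subset_size: int, seed: int,
                          core_fraction: float = 0.75) -> PairedRarefaction:
    """Oversampling-bias check: sample at a fixed subset size from the full
    strain set and from the set with a (closely related) clade excluded."""
    labels, mat = _as_matrix(presence)
    exclude = set(exclude)
    unknown = exclude - set(labels)
    if unknown:
        raise ValueError(f"exclude lists unknown strains: {sorted(unknown)}")
    keep = [i for i, lab in enumerate(labels) if lab not in exclude]
    if len(keep) < subset_size:
        raise ValueError(
            f"subset_size {subset_size} exceeds {len(keep)} strains "
            f"remaining after exclusion")
    if not (1 <= subset_size <= mat.shape[0]):
        raise ValueError("subset_size out of range")
    rng_full = np.random.default_rng(seed)
    rng_red = np.random.default_rng(seed)
    fc, fp = _sample_at(mat, subset_size, n_samples, rng_full,
                        core_fraction, False)
    rc, rp = _sample_at(mat[keep], subset_size, n_samples, rng_red,
                        core_fraction, False)
    return PairedRarefaction(
        subset_size=subset_size,
        full_core=lower_median(fc), full_pan=lower_median(fp),
        reduced_core=lower_median(rc), reduced_pan=lower_median(rp),
        full_core_samples=fc, full_pan_samples=fp,
        reduced_core_samples=rc, reduced_pan_samples=rp)
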