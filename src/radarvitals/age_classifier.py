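"""Age-group classification from range-FFT images.

Each participant contributes one 30 s range-FFT magnitude image
(slow time × range bins, log-compressed and min-max normalized).  The
image's subject column is modulated at the breathing and heartbeat
frequencies, which fall with age, so the temporal spectrum of that column
carries age information.  Three grouping schemes partition ages [0, 13):
four groups {0,3,6,9,13}, three groups {0,4,8,13}, and two groups
{0,6,13} (boundary ages belong to the older group).

The split is participant-wise and stratified: test participants are
allocated across groups proportionally to group sizes (largest-remainder
rounding) so every group is represented when feasible, and no participant
contributes images to both sides.

The classifier backend is pluggable (``fit(X, y)`` / ``predict(X)``); the
shipped reference backend is a deterministic nearest-centroid classifier
on spectral features of the subject column.  Heavier image models (CNNs)
can be dropped in through the same interface.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np

from .errors import ConfigurationError, ShapeError
from .radar_model import RadarCube
from .vitals_extraction import range_fft

__all__ = [
    "AgeGroupScheme",
    "RangeImage",
    "SplitPlan",
    "builtin_schemes",
    "render_range_image",
    "make_split",
    "evaluate",
    "SpectralCentroidBackend",
    "train_and_test",
]

IMAGE_SECONDS = 30.0  #: slow-time extent of one classification image


@dataclass(frozen=True)
class AgeGroupScheme:
    """Partition of [0, 13) years into labeled half-open intervals.

    Interval i is [boundaries[i], boundaries[i+1]); the last interval is
    closed at 13.  A boundary age belongs to the older group.
    """

    boundaries: tuple[float, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        b = self.boundaries
        if b[0] != 0 or b[-1] != 13 or any(x >= y for x, y in zip(b, b[1:])):
            raise ConfigurationError("boundaries must ascend from 0 to 13")
        if len(self.labels) != len(b) - 1:
            raise ConfigurationError("need one label per interval")

    @property
    def n_groups(self) -> int:
        return len(self.labels)

    def assign(self, age: float) -> str:
        if not (0 <= age <= 13):
            raise ConfigurationError(f"age {age} outside [0, 13]")
        idx = int(np.searchsorted(self.boundaries, age, side="right")) - 1
        return self.labels[min(idx, self.n_groups - 1)]


def builtin_schemes() -> tuple[AgeGroupScheme, AgeGroupScheme, AgeGroupScheme]:
    """The three study grouping schemes: 4-, 3-, and 2-group."""
    four = AgeGroupScheme((0, 3, 6, 9, 13), ("0-3", "3-6", "6-9", "9-13"))
    three = AgeGroupScheme((0, 4, 8, 13), ("0-4", "4-8", "8-13"))
    two = AgeGroupScheme((0, 6, 13), ("0-6", "6-13"))
    return four, three, two


@dataclass
class RangeImage:
    """Normalized 30 s range-FFT magnitude image for one participant."""

    pixels: np.ndarray  # [slow time x range bins], values in [0, 1]
    participant_id: int = -1
    label: str = ""
    slow_time_rate: float = 20.0


@dataclass
class SplitPlan:
    """Participant-disjoint train/test id lists."""

    train_ids: list[int]
    test_ids: list[int]

    def __post_init__(self) -> None:
        if set(self.train_ids) & set(self.test_ids):
            raise ConfigurationError("train and test ids overlap")


def render_range_image(cube: RadarCube, start: float = 0.0,
                       participant_id: int = -1, label: str = "") -> RangeImage:
    """Render 30 s of a cube as a normalized log-magnitude range-FFT image."""
    fps = cube.config.frames_per_second
    f0 = int(round(start * fps))
    n_rows = int(round(IMAGE_SECONDS * fps))
    if f0 < 0 or f0 + n_rows > cube.n_frames:
        raise ShapeError(
            f"cube holds {cube.n_frames} frames; need frames [{f0}, {f0 + n_rows})"
        )
    sub = RadarCube(cube.data[f0:f0 + n_rows], cube.config,
                    start_time=cube.start_time + start)
    rpm = range_fft(sub)
    mag = np.log1p(np.abs(rpm.profiles))
    lo, hi = mag.min(), mag.max()
    pixels = np.zeros_like(mag) if hi <= lo else (mag - lo) / (hi - lo)
    return RangeImage(pixels=pixels, participant_id=participant_id, label=label,
                      slow_time_rate=float(fps))


def make_split(cohort, scheme: AgeGroupScheme, n_test: int, seed: int = 0) -> SplitPlan:
    """Stratified participant-wise split.

    Test quotas are allocated across age groups proportionally to group
    sizes with largest-remainder rounding; members are sampled within each
    group by ``seed``.  A quota that cannot be filled from its group is
    reassigned to the largest remaining groups with a warning.
    """
    if n_test >= len(cohort):
        raise ConfigurationError("n_test must be smaller than the cohort")
    rng = np.random.default_rng(seed)
    groups: dict[str, list[int]] = {lab: [] for lab in scheme.labels}
    for meta in cohort:
        groups[scheme.assign(meta.age)].append(meta.id)
    sizes = np.array([len(groups[lab]) for lab in scheme.labels], dtype=float)
    total = sizes.sum()
    quotas = np.zeros(len(sizes), dtype=int)
    if n_test > 0 and total > 0:
        exact = n_test * sizes / total
        quotas = np.floor(exact).astype(int)
        remainder = exact - quotas
        for i in np.argsort(-remainder)[: n_test - quotas.sum()]:
            quotas[i] += 1
    # reassign quotas that exceed group membership
    overflow = int(np.maximum(quotas - sizes.astype(int), 0).sum())
    quotas = np.minimum(quotas, sizes.astype(int))
    while overflow > 0:
        room = sizes.astype(int) - quotas
        if room.max() <= 0:
            break
        j = int(np.argmax(room))
        quotas[j] += 1
        overflow -= 1
        warnings.warn("stratification quota reassigned (empty or small group)",
                      stacklevel=2)
    test_ids: list[int] = []
    for lab, q in zip(scheme.labels, quotas):
        ids = sorted(groups[lab])
        pick = rng.choice(len(ids), size=int(q), replace=False)
        test_ids.extend(ids[i] for i in sorted(pick))
    test_set = set(test_ids)
    train_ids = [m.id for m in cohort if m.id not in test_set]
    return SplitPlan(train_ids=train_ids, test_ids=sorted(test_ids))


def evaluate(predictions, truth, scheme: AgeGroupScheme) -> tuple[np.ndarray, float]:
    """Confusion matrix (rows = truth, columns = predicted) and accuracy."""
    predictions = list(predictions)
    truth = list(truth)
    if len(predictions) != len(truth):
        raise ShapeError("prediction/truth length mismatch")
    index = {lab: i for i, lab in enumerate(scheme.labels)}
    for lab in set(predictions) | set(truth):
        if lab not in index:
            raise ConfigurationError(f"label {lab!r} not in scheme")
    k = scheme.n_groups
    cm = np.zeros((k, k), dtype=int)
    for t, p in zip(truth, predictions):
        cm[index[t], index[p]] += 1
    acc = float(np.trace(cm) / cm.sum()) if cm.sum() else 0.0
    return cm, acc


class SpectralCentroidBackend:
    """Deterministic nearest-centroid classifier on subject-column spectra.

    Features per image: the dominant temporal frequency (Hz) of the
    highest-variance range column within the breathing band [0.1, 0.7] and
    the heartbeat band [0.9, 3.0], plus the band log-energy ratio.  Features
    are z-scored with the training statistics; prediction picks the nearest
    class centroid in that space.
    """

    def __init__(self, br_band=(0.1, 0.7), hr_band=(0.9, 3.0)):
        self.br_band = br_band
        self.hr_band = hr_band
        self._centroids: dict[str, np.ndarray] = {}
        self._mu: np.ndarray | None = None
        self._sigma: np.ndarray | None = None

    def features(self, image: RangeImage) -> np.ndarray:
        px = image.pixels
        col = px[:, int(np.argmax(px.var(axis=0)))]
        col = col - col.mean()
        n_fft = int(2 ** np.ceil(np.log2(len(col) * 4)))
        spec = np.abs(np.fft.rfft(col * np.hanning(len(col)), n=n_fft))
        freqs = np.fft.rfftfreq(n_fft, d=1.0 / image.slow_time_rate)

        def band_peak(band):
            m = (freqs >= band[0]) & (freqs <= band[1])
            i = np.flatnonzero(m)
            return freqs[i[np.argmax(spec[i])]], float(np.sum(spec[i] ** 2))

        fb, eb = band_peak(self.br_band)
        fh, eh = band_peak(self.hr_band)
        return np.array([fb, fh, np.log10((eb + 1e-12) / (eh + 1e-12))])

    def fit(self, images: list[RangeImage], labels: list[str]) -> "SpectralCentroidBackend":
        X = np.array([self.features(im) for im in images])
        self._mu = X.mean(axis=0)
        self._sigma = np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
        Z = (X - self._mu) / self._sigma
        self._centroids = {
            lab: Z[np.array(labels) == lab].mean(axis=0) for lab in set(labels)
        }
        return self

    def predict(self, images: list[RangeImage]) -> list[str]:
        if not self._centroids:
            raise RuntimeError("backend not fitted")
        Z = (np.array([self.features(im) for im in images]) - self._mu) / self._sigma
        labs = sorted(self._centroids)
        cents = np.array([self._centroids[lab] for lab in labs])
        out = []
        for z in Z:
            out.append(labs[int(np.argmin(np.linalg.norm(cents - z, axis=1)))])
        return out


def train_and_test(
    bundle,
    scheme: AgeGroupScheme,
    split: SplitPlan,
    backend=None,
    seed: int = 0,
    start: float = 0.0,
    shuffle_labels: bool = False,
) -> dict:
    """Render per-participant images, fit the backend on the training split,
    and evaluate on the held-out participants.

    ``bundle`` is anything exposing ``load_cube(pid)`` and ``load_cohort()``
    (an on-disk bundle or an in-memory study adapter).  ``shuffle_labels``
    permutes the training labels (null control).  Returns a dict with the
    confusion matrix, accuracy, per-id predictions, and the split.
    """
    backend = backend if backend is not None else SpectralCentroidBackend()
    cohort = {m.id: m for m in bundle.load_cohort()}
    for pid in split.train_ids + split.test_ids:
        if pid not in cohort:
            raise ConfigurationError(f"split references unknown participant {pid}")

    def image(pid):
        return render_range_image(bundle.load_cube(pid), start=start,
                                  participant_id=pid,
                                  label=scheme.assign(cohort[pid].age))

    train_imgs = [image(pid) for pid in split.train_ids]
    train_labels = [im.label for im in train_imgs]
    if shuffle_labels:
        rng = np.random.default_rng(seed)
        train_labels = [train_labels[i] for i in rng.permutation(len(train_labels))]
    backend.fit(train_imgs, train_labels)
    test_imgs = [image(pid) for pid in split.test_ids]
    truth = [im.label for im in test_imgs]
    preds = backend.predict(test_imgs)
    cm, acc = evaluate(preds, truth, scheme)
    return {
        "confusion_matrix": cm,
        "accuracy": acc,
        "predictions": dict(zip(split.test_ids, preds)),
        "truth": dict(zip(split.test_ids, truth)),
        "scheme": scheme,
        "split": split,
    }
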