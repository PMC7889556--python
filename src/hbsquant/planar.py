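"""Dynamic planar processing: time-activity curves and geometric means.

A dual-head gamma camera records anterior and posterior projections of
the same activity distribution simultaneously.  Because photon
attenuation depends on source depth, neither single view is
quantitative; the geometric mean sqrt(anterior x posterior) of the two
opposed views cancels the depth dependence to first order.  Two modes
are in clinical use and give systematically different results:

* ROI-ROI — sum counts inside the region of interest separately on
  each view, then take the geometric mean of the two sums.
* pixel-pixel — combine the two views into a single geometric-mean
  image pixel by pixel, then sum inside the ROI.

By the Cauchy-Schwarz inequality the pixel-pixel ROI sum never exceeds
the ROI-ROI value, with equality only when the anterior/posterior pixel
ratio is constant over the ROI.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FrameStack",
    "ROISet",
    "TimeActivityCurve",
    "extract_tac",
    "gmean_roi",
    "gmean_pixel",
]


@dataclass(frozen=True)
class FrameStack:
    """Ordered 2-D count frames for one planar view.

    Parameters
    ----------
    view:
        ``"anterior"``, ``"posterior"`` or ``"gmean"``.
    frames:
        Array of shape ``(n_frames, ny, nx)`` with nonnegative counts.
    frame_mid_times:
        Mid-acquisition time of each frame in seconds, strictly
        increasing.
    """

    view: str
    frames: np.ndarray
    frame_mid_times: np.ndarray
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=float)
        times = np.asarray(self.frame_mid_times, dtype=float)
        if frames.ndim != 3:
            raise ValueError(f"frames must be 3-D (n, ny, nx), got ndim={frames.ndim}")
        if times.ndim != 1 or len(times) != frames.shape[0]:
            raise ValueError("frame_mid_times length must match number of frames")
        if np.any(np.diff(times) <= 0):
            raise ValueError("frame_mid_times must be strictly increasing")
        if np.any(frames < 0):
            raise ValueError("frame counts must be nonnegative")
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "frame_mid_times", times)

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass(frozen=True)
class ROISet:
    """Planar regions of interest: total liver, blood pool, field of view.

    The blood-pool ROI is drawn over the heart / large vessels; the
    field-of-view ROI defaults to the full matrix.  Liver and blood
    pool must not overlap and both must lie inside the field of view.
    """

    liver: np.ndarray
    bloodpool: np.ndarray
    fov: np.ndarray | None = None

    def __post_init__(self) -> None:
        liver = np.asarray(self.liver, dtype=bool)
        blood = np.asarray(self.bloodpool, dtype=bool)
        fov = np.ones_like(liver) if self.fov is None else np.asarray(self.fov, dtype=bool)
        if liver.shape != blood.shape or liver.shape != fov.shape:
            raise ValueError("ROI masks must share one shape")
        if not liver.any() or not blood.any():
            raise ValueError("liver and bloodpool ROIs must be nonempty")
        if (liver & blood).any():
            raise ValueError("liver and bloodpool ROIs overlap")
        if (liver & ~fov).any() or (blood & ~fov).any():
            raise ValueError("liver and bloodpool ROIs must lie inside the FOV ROI")
        object.__setattr__(self, "liver", liver)
        object.__setattr__(self, "bloodpool", blood)
        object.__setattr__(self, "fov", fov)


@dataclass(frozen=True)
class TimeActivityCurve:
    """Per-frame summed counts for one region."""

    region: str
    times: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        counts = np.asarray(self.counts, dtype=float)
        if times.shape != counts.shape or times.ndim != 1:
            raise ValueError("times and counts must be equal-length 1-D arrays")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(counts < 0):
            raise ValueError("counts must be nonnegative")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "counts", counts)

    def __len__(self) -> int:
        return len(self.times)


def extract_tac(stack: FrameStack, mask: np.ndarray, region: str = "roi") -> TimeActivityCurve:
    """Sum counts inside ``mask`` on every frame of ``stack``.

    Raises
    ------
    ValueError
        If the mask is empty or does not match the frame shape.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != stack.shape:
        raise ValueError(f"mask shape {mask.shape} does not match frames {stack.shape}")
    if not mask.any():
        raise ValueError("ROI mask is empty")
    counts = stack.frames[:, mask].sum(axis=1)
    return TimeActivityCurve(region=region, times=stack.frame_mid_times, counts=counts)


def _check_common_grid(a: TimeActivityCurve, b: TimeActivityCurve) -> None:
    if len(a) != len(b) or not np.allclose(a.times, b.times):
        raise ValueError("time grids of the two curves differ")


def gmean_roi(tac_ant: TimeActivityCurve, tac_post: TimeActivityCurve) -> TimeActivityCurve:
    """ROI-ROI geometric mean of two opposed-view curves.

    ``counts[i] = sqrt(anterior[i] * posterior[i])`` frame by frame.
    """
    _check_common_grid(tac_ant, tac_post)
    counts = np.sqrt(tac_ant.counts * tac_post.counts)
    return TimeActivityCurve(region=tac_ant.region, times=tac_ant.times, counts=counts)


def gmean_pixel(
    stack_ant: FrameStack,
    stack_post: FrameStack,
    mirror_posterior: bool = True,
) -> FrameStack:
    """Pixel-pixel geometric-mean image stack of opposed views.

    The posterior camera head views the patient from behind, so its
    image is the left-right mirror of the anterior geometry; by default
    it is flipped back before combination so that anterior-orientation
    ROI masks apply to the result.
    """
    if stack_ant.frames.shape != stack_post.frames.shape:
        raise ValueError("anterior and posterior stacks differ in shape")
    if not np.allclose(stack_ant.frame_mid_times, stack_post.frame_mid_times):
        raise ValueError("anterior and posterior stacks differ in frame timing")
    post = stack_post.frames
    if mirror_posterior:
        post = post[:, :, ::-1]
    frames = np.sqrt(stack_ant.frames * post)
    return FrameStack(
        view="gmean",
        frames=frames,
        frame_mid_times=stack_ant.frame_mid_times,
        meta={"mirror_posterior": mirror_posterior},
    )
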