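"""The eight user-adjustable analysis parameters, persisted as a profile.

A :class:`ParameterProfile` captures everything the analysis needs beyond
the image itself, so a profile tuned once on a representative image (the
"sandbox" workflow) can drive fully automated batch analysis of an entire
study.  Profiles are stored as flat JSON with a ``version`` key; the Clip
parameter admits the sentinel token ``"Inf"`` meaning "iterate until the
mask no longer changes".

Defaults sit at the midpoint of each parameter's typical working range
(Scale 0.5–5 µm/px, Canny 2–12 px, Dilate 2–7 px, Fill 200–5000 px²,
Clean 1000–10000 px², Clip 50–Inf, Overlap 10 px, Radius 30–150 px).
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import asdict, dataclass, replace
from pathlib import Path

#: Sentinel for an unbounded Clip: spur removal iterates to a fixed point,
#: eliminating branch-free components entirely.
INFINITE = math.inf

PROFILE_VERSION = 1

_FIELDS = ("scale", "canny_connect", "dilate", "fill", "clean", "clip", "overlap", "radius")


class ProfileError(ValueError):
    """A profile field is missing or outside its valid domain."""


@dataclass(frozen=True)
class ParameterProfile:
    """Analysis parameters for one tube-formation-assay image set.

    Parameters
    ----------
    scale : float
        Pixel scaling in microns per pixel (e.g. 1 pixel = 1.8 µm); > 0.
    canny_connect : int
        Radius (px) within which detected edge points are connected
        (morphological closing) after the Canny step.
    dilate : int
        Radius (px) of a second closing pass that merges nearby objects
        and suppresses noise.
    fill : int
        Enclosed background regions (holes) strictly smaller than this
        many pixels are filled in (false-negative repair).
    clean : int
        Foreground objects strictly smaller than this many pixels are
        cleared (false-positive removal).
    clip : float
        Number of pixels trimmed from every skeleton endpoint, stopping
        early at a branch intersection; :data:`INFINITE` trims until the
        skeleton stops changing, removing branch-free tubes entirely.
    overlap : int
        A detected object must share at least this many pixels with the
        skeleton for its area to be counted.
    radius : int
        Branch points within this radius are spatially averaged into a
        single node.
    """

    scale: float = 2.75
    canny_connect: int = 7
    dilate: int = 4
    fill: int = 2600
    clean: int = 5500
    clip: float = 50
    overlap: int = 10
    radius: int = 90

    def __post_init__(self) -> None:
        if not (isinstance(self.scale, (int, float)) and math.isfinite(self.scale) and self.scale > 0):
            raise ProfileError(f"scale must be a finite positive number, got {self.scale!r}")
        for key in ("canny_connect", "dilate", "fill", "clean", "overlap", "radius"):
            v = getattr(self, key)
            if not (isinstance(v, int) and not isinstance(v, bool) and v >= 0):
                raise ProfileError(f"{key} must be a non-negative integer, got {v!r}")
        c = self.clip
        ok = isinstance(c, (int, float)) and not isinstance(c, bool) and c >= 0
        if ok and math.isfinite(c) and float(c) != int(c):
            ok = False
        if not ok:
            raise ProfileError(f"clip must be a non-negative integer or INFINITE, got {c!r}")

    def with_overrides(self, **kwargs) -> "ParameterProfile":
        """Return a copy with the given fields replaced (validated)."""
        return replace(self, **{k: v for k, v in kwargs.items() if v is not None})


def save_profile(profile: ParameterProfile, path) -> Path:
    """Write *profile* to *path* as human-readable JSON.

    ``clip = INFINITE`` is serialized as the literal token ``"Inf"``.
    """
    path = Path(path)
    data = asdict(profile)
    if math.isinf(data["clip"]):
        data["clip"] = "Inf"
    else:
        data["clip"] = int(data["clip"])
    data = {"version": PROFILE_VERSION, **data}
    path.write_text(json.dumps(data, indent=2) + "\n")
    return path


def load_profile(path) -> ParameterProfile:
    """Read and validate a profile written by :func:`save_profile`.

    Unknown keys produce a warning, not a failure; a missing or
    out-of-domain field raises :class:`ProfileError` naming the key.
    """
    path = Path(path)
    try:
        data = json.loads(path.read_text())
    except FileNotFoundError:
        raise
    except json.JSONDecodeError as exc:
        raise ProfileError(f"profile file {path} is not valid JSON: {exc}") from exc
    if not isinstance(data, dict):
        raise ProfileError(f"profile file {path} must contain a JSON object")

    extra = set(data) - set(_FIELDS) - {"version"}
    if extra:
        warnings.warn(f"ignoring unknown profile keys: {sorted(extra)}", stacklevel=2)

    kwargs = {}
    for key in _FIELDS:
        if key not in data:
            raise ProfileError(f"profile is missing required key {key!r}")
        kwargs[key] = data[key]

    clip = kwargs["clip"]
    if isinstance(clip, str):
        if clip.strip().lower() in {"inf", "infinite", "infinity"}:
            kwargs["clip"] = INFINITE
        else:
            raise ProfileError(f"clip must be a non-negative integer or 'Inf', got {clip!r}")
    return ParameterProfile(**kwargs)
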