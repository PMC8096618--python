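"""Synthetic orientation-cage datasets.

The study's raw cage records are not deposited, so this module generates
datasets with the statistical structure the analysis pipeline assumes:
per-group von Mises headings matched to the published group mean
directions, mean vector lengths and sample sizes, rounded to the 5-degree
reading granularity of funnel papers, with activity/concentration scores,
fat scores, capture-window dates, session times shortly before local
sunset, and a pool of inactive tests.

Default group parameters are the study's printed (alpha, r, n) per group;
inactivity rates default to the printed sky-condition split (44% of
overcast tests vs 17% of clear-sky tests inactive).
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from datetime import date as _date
from datetime import timedelta

import numpy as np
import pandas as pd

from .circstats import vonmises_kappa
from .geometry import STUDY_SITE
from .solar import sunset_instant

CAPTURE_WINDOWS = {"early": (_date(2005, 8, 8), _date(2005, 8, 11)),
                   "late": (_date(2005, 9, 4), _date(2005, 9, 9))}
SESSION_WINDOWS = {"early": (_date(2005, 8, 11), _date(2005, 8, 31)),
                   "late": (_date(2005, 9, 4), _date(2005, 9, 19))}

COLUMNS = [
    "bird_id", "age", "capture_window", "sky", "fat_score", "bearing",
    "activity_score", "concentration_score", "session_date", "session_time_utc",
    "sun_azimuth",
]


@dataclass(frozen=True)
class GroupSpec:
    """Target statistical structure of one experimental cell."""

    label: str
    n: int
    mu: float  # group mean direction, degrees
    r_target: float  # target mean vector length, sets kappa = A^-1(r)
    age: str  # 'adult' | 'juvenile'
    capture_window: str  # 'early' | 'late'
    sky: str  # 'clear' | 'overcast_natural' | 'overcast_simulated'
    inactive_fraction: float = 0.17
    fat_scores: tuple = tuple(range(0, 7))  # plausible visual fat classes

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not 0.0 <= self.r_target < 1.0:
            raise ValueError("r_target must be in [0, 1)")
        if not 0.0 <= self.inactive_fraction <= 1.0:
            raise ValueError("inactive_fraction must be in [0, 1]")


# The five elementary cells reported by the study; the pooled juvenile
# diagrams arise as unions of the early/late juvenile cells.
STUDY_GROUPS = (
    GroupSpec("adult_clear", 16, 114.0, 0.61, "adult", "early", "clear",
              inactive_fraction=0.17),
    GroupSpec("early_juv_clear", 22, 113.0, 0.47, "juvenile", "early", "clear",
              inactive_fraction=0.17),
    GroupSpec("late_juv_clear", 21, 221.0, 0.37, "juvenile", "late", "clear",
              inactive_fraction=0.17),
    GroupSpec("early_juv_overcast", 23, 116.0, 0.40, "juvenile", "early",
              "overcast_natural", inactive_fraction=0.44),
    GroupSpec("late_juv_overcast", 22, 178.0, 0.42, "juvenile", "late",
              "overcast_natural", inactive_fraction=0.44),
)

_SUNSET_CACHE: dict = {}


def _session_datetime(rng, window):
    """Random session date in the window, starting <= 1.5 h before local sunset."""
    d0, d1 = SESSION_WINDOWS[window]
    day = d0 + timedelta(days=int(rng.integers(0, (d1 - d0).days + 1)))
    if day not in _SUNSET_CACHE:
        _SUNSET_CACHE[day] = sunset_instant(STUDY_SITE, day)
    sunset = _SUNSET_CACHE[day]
    start = sunset - timedelta(minutes=float(rng.uniform(0.0, 90.0)))
    return day, start


def _draw_scores(rng, size):
    """Activity/concentration scores in 1..4 satisfying the inclusion rule."""
    act = rng.integers(1, 5, size=size)
    conc = rng.integers(1, 5, size=size)
    bad = act + conc < 3
    while bad.any():
        act[bad] = rng.integers(1, 5, size=int(bad.sum()))
        conc[bad] = rng.integers(1, 5, size=int(bad.sum()))
        bad = act + conc < 3
    return act, conc


def generate_group(spec: GroupSpec, seed, id_offset: int = 0) -> pd.DataFrame:
    """Generate one cell: ``spec.n`` included records plus inactive extras.

    Fully reproducible from ``seed``.  Bearings are drawn von Mises with
    kappa = A^-1(r_target) around ``spec.mu`` and rounded to the nearest
    5 degrees; the inactive pool (activity score 0, excluded by the
    analysis) is sized so that inactive tests are ``inactive_fraction`` of
    all tests in the cell.
    """
    rng = np.random.default_rng(seed)
    kappa = vonmises_kappa(spec.r_target)
    n = spec.n
    bearings = np.degrees(rng.vonmises(np.radians(spec.mu), kappa, size=n))
    bearings = np.mod(np.round(bearings / 5.0) * 5.0, 360.0)
    act, conc = _draw_scores(rng, n)
    f = spec.inactive_fraction
    n_inactive = int(round(n * f / (1.0 - f))) if f < 1.0 else 0

    rows = []
    from .solar import sun_altaz_arrays, julian_day  # local import to avoid cycle

    for i in range(n):
        day, start = _session_datetime(rng, spec.capture_window)
        mid = start + timedelta(minutes=30)
        az, _ = sun_altaz_arrays(STUDY_SITE.lat, STUDY_SITE.lon, julian_day(mid))
        rows.append({
            "bird_id": f"{spec.label}_{id_offset + i:03d}",
            "age": spec.age,
            "capture_window": spec.capture_window,
            "sky": spec.sky,
            "fat_score": int(rng.choice(spec.fat_scores)),
            "bearing": float(bearings[i]),
            "activity_score": int(act[i]),
            "concentration_score": int(conc[i]),
            "session_date": day.isoformat(),
            "session_time_utc": start.strftime("%H:%M:%S"),
            "sun_azimuth": round(float(az), 1),
        })
    # inactive tests: same birds retested on an earlier day, activity 0
    for j in range(n_inactive):
        src = rows[int(rng.integers(0, n))]
        day, start = _session_datetime(rng, spec.capture_window)
        rows.append({**src,
                     "bearing": float(rng.integers(0, 72) * 5),
                     "activity_score": 0,
                     "concentration_score": int(rng.integers(0, 2)),
                     "session_date": day.isoformat(),
                     "session_time_utc": start.strftime("%H:%M:%S")})
    df = pd.DataFrame(rows, columns=COLUMNS)
    return df.sort_values(["session_date", "session_time_utc"], kind="stable").reset_index(drop=True)


def generate_study(seed) -> pd.DataFrame:
    """The default full dataset: all study cells with their printed parameters."""
    seq = np.random.SeedSequence(seed)
    frames = []
    for spec, child in zip(STUDY_GROUPS, seq.spawn(len(STUDY_GROUPS))):
        frames.append(generate_group(spec, child, id_offset=0))
    return pd.concat(frames, ignore_index=True)
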