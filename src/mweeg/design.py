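"""Factorial clip set, counterbalanced presentation versions, probe schedules.

The task presents 5-minute videoclips whose audio and image tracks are
factorially recombined across n source films: n clips keep their original
(synchronized) soundtrack and n*(n-1) pair image and audio from different
films (non-synchronized). Each presentation version shows 2 synchronized and
2 non-synchronized experimental clips (plus one practice clip) such that no
film contributes to two clips within a version, and across the 6 versions
every film serves as the synchronized source equally often and the
non-synchronized image/audio usage is balanced.

During each video, probes interrupt playback every 60 +/- 10 s and the
participant reports their momentary cognitive state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Clip",
    "Version",
    "DesignError",
    "build_clip_set",
    "build_versions",
    "validate_versions",
    "schedule_probes",
]

SYNC = "Sync"
NOSYNC = "NoSync"


class DesignError(ValueError):
    pass


@dataclass(frozen=True)
class Clip:
    image_film: int
    audio_film: int

    @property
    def synchrony(self) -> str:
        return SYNC if self.image_film == self.audio_film else NOSYNC

    @property
    def films(self) -> set[int]:
        return {self.image_film, self.audio_film}


@dataclass(frozen=True)
class Version:
    id: int
    clips: tuple[Clip, ...]  # 4 experimental clips, 2 Sync then 2 NoSync
    practice: Clip = field(default=Clip(-1, -1))


def build_clip_set(n_films: int) -> list[Clip]:
    """All n^2 factorial (image, audio) pairings: n Sync + n(n-1) NoSync."""
    if n_films < 2:
        raise DesignError(f"need at least 2 films, got {n_films}")
    return [Clip(i, a) for i in range(n_films) for a in range(n_films)]


def _film_counts(versions: list[Version]) -> dict[str, np.ndarray]:
    n_films = 1 + max(f for v in versions for c in v.clips for f in c.films)
    sync = np.zeros(n_films, dtype=int)
    ns_image = np.zeros(n_films, dtype=int)
    ns_audio = np.zeros(n_films, dtype=int)
    for v in versions:
        for c in v.clips:
            if c.synchrony == SYNC:
                sync[c.image_film] += 1
            else:
                ns_image[c.image_film] += 1
                ns_audio[c.audio_film] += 1
    return {"sync": sync, "ns_image": ns_image, "ns_audio": ns_audio}


def validate_versions(versions: list[Version], n_films: int = 6) -> list[str]:
    """Re-check every printed design constraint; returns a list of violations.

    An empty list means the versions satisfy: 2 Sync + 2 NoSync experimental
    clips each, film-uniqueness within a version (practice exempt), every film
    Sync-source exactly twice across versions, and balanced NoSync usage.
    """
    problems: list[str] = []
    for v in versions:
        syncs = [c for c in v.clips if c.synchrony == SYNC]
        nosyncs = [c for c in v.clips if c.synchrony == NOSYNC]
        if len(syncs) != 2 or len(nosyncs) != 2:
            problems.append(f"version {v.id}: expected 2 Sync + 2 NoSync, got "
                            f"{len(syncs)}+{len(nosyncs)}")
        used: list[int] = []
        for c in v.clips:
            used.extend(sorted(c.films))
        if len(used) != len(set(used)):
            problems.append(f"version {v.id}: a film is used by two clips")
    counts = _film_counts(versions)
    n_versions = len(versions)
    want_sync = 2 * n_versions // n_films
    if not np.all(counts["sync"][:n_films] == want_sync):
        problems.append(f"sync usage per film {counts['sync'].tolist()} != {want_sync}")
    for key in ("ns_image", "ns_audio"):
        c = counts[key][:n_films]
        if c.max() - c.min() > 0:
            problems.append(f"{key} usage unbalanced: {c.tolist()}")
    return problems


def build_versions(
    clips: list[Clip],
    n_versions: int = 6,
    seed: int = 0,
    max_expansions: int = 10_000,
    practice_film: int | None = None,
) -> list[Version]:
    """Randomized backtracking search for counterbalanced versions.

    Each version takes 2 Sync and 2 NoSync clips over distinct films, with
    global balance: each film Sync-source 2*n_versions/n_films times, and each
    film used once as NoSync image and once as NoSync audio per every 3
    versions (uniform targets). The practice clip is a Sync clip of a
    dedicated film outside the experimental set and is exempt from the
    uniqueness constraint. Deterministic given seed; raises DesignError when
    the bounded search is exhausted.
    """
    n_films = 1 + max(f for c in clips for f in c.films)
    if (2 * n_versions) % n_films != 0:
        raise DesignError(
            f"{n_versions} versions with {n_films} films cannot balance Sync usage"
        )
    sync_target = 2 * n_versions // n_films
    if (2 * n_versions) % n_films != 0:
        raise DesignError("NoSync balance infeasible")
    ns_target = 2 * n_versions // n_films
    rng = np.random.default_rng(seed)
    sync_clips = [c for c in clips if c.synchrony == SYNC]
    nosync_clips = [c for c in clips if c.synchrony == NOSYNC]

    sync_used = np.zeros(n_films, dtype=int)
    ns_img_used = np.zeros(n_films, dtype=int)
    ns_aud_used = np.zeros(n_films, dtype=int)
    expansions = 0

    def candidates(version_clips: list[Clip], want_sync: bool) -> list[Clip]:
        used = set().union(*[c.films for c in version_clips]) if version_clips else set()
        if want_sync:
            pool = [c for c in sync_clips
                    if not (c.films & used) and sync_used[c.image_film] < sync_target]
        else:
            pool = [c for c in nosync_clips
                    if not (c.films & used)
                    and ns_img_used[c.image_film] < ns_target
                    and ns_aud_used[c.audio_film] < ns_target]
        order = rng.permutation(len(pool))
        return [pool[i] for i in order]

    def apply(c: Clip, sign: int) -> None:
        if c.synchrony == SYNC:
            sync_used[c.image_film] += sign
        else:
            ns_img_used[c.image_film] += sign
            ns_aud_used[c.audio_film] += sign

    def solve(v_idx: int, version_clips: list[Clip], done: list[list[Clip]]) -> bool:
        nonlocal expansions
        if v_idx == n_versions:
            return True
        slot = len(version_clips)
        if slot == 4:
            done.append(version_clips)
            if solve(v_idx + 1, [], done):
                return True
            done.pop()
            return False
        for c in candidates(version_clips, want_sync=slot < 2):
            expansions += 1
            if expansions > max_expansions:
                raise DesignError(
                    f"backtracking budget of {max_expansions} expansions exhausted"
                )
            apply(c, +1)
            if solve(v_idx, version_clips + [c], done):
                return True
            apply(c, -1)
        return False

    done: list[list[Clip]] = []
    if not solve(0, [], done):
        raise DesignError("no counterbalanced assignment found")

    pf = practice_film if practice_film is not None else n_films
    practice = Clip(pf, pf)
    versions = [
        Version(id=i + 1, clips=tuple(vc), practice=practice)
        for i, vc in enumerate(done)
    ]
    problems = validate_versions(versions, n_films)
    if problems:  # the validator, not the constructor, is the source of truth
        raise DesignError("constructed versions failed validation: " + "; ".join(problems))
    return versions


def schedule_probes(
    video_length_s: float,
    mean_gap_s: float = 60.0,
    jitter_s: float = 10.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Probe onset times: successive gaps ~ U(mean-jitter, mean+jitter).

    Times are strictly increasing and never exceed the video length; a video
    shorter than the minimum gap yields an empty schedule.
    """
    if not mean_gap_s > jitter_s >= 0:
        raise DesignError("require mean_gap_s > jitter_s >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    times: list[float] = []
    t = 0.0
    while True:
        t += rng.uniform(mean_gap_s - jitter_s, mean_gap_s + jitter_s)
        if t > video_length_s:
            break
        times.append(t)
    return np.asarray(times)
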