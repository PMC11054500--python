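"""Sample-exclusion rules for noisy GNSS fixes, with removal provenance.

Six rules are evaluated per sample, in order; a sample is removed by the
first rule it fails and the rule id is recorded:

R1  altitude absent (fix not computed from satellites),
R2  accuracy radius above 25 m,
R3  mean acceleration magnitude below 0.5 m/s^2 (user likely standing),
R4  step count unchanged versus the last kept sample (no movement),
R5  time delta versus the last kept sample <= 0 (stale fix replayed),
R6  implied speed versus the last kept sample above 5 m/s.

Pairwise rules (R4-R6) compare against the last KEPT sample so a single
bad fix cannot shield the one after it. R3 and R4 are skipped when their
channel is absent (inertial data are not available on every recording).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .trace import GnssSample, WalkTrace, haversine_m

RULE_IDS = ("R1", "R2", "R3", "R4", "R5", "R6")


@dataclass(frozen=True)
class FilterThresholds:
    """Exclusion-rule configuration; defaults are the published values."""

    max_accuracy_m: float = 25.0
    min_accel_mag: float = 0.5
    max_speed_mps: float = 5.0
    #: accuracy a fix must reach before the test is considered started;
    #: only used when ``trim_leading`` is on (the app's start condition).
    start_accuracy_m: float = 15.0
    trim_leading: bool = False

    def __post_init__(self) -> None:
        for name in ("max_accuracy_m", "min_accel_mag", "max_speed_mps", "start_accuracy_m"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class FilterReport:
    """Outcome of :func:`apply_filters`.

    ``removed`` holds (original sample index, rule id) pairs; every input
    sample is either kept or removed exactly once.
    """

    kept: WalkTrace
    removed: list[tuple[int, str]] = field(default_factory=list)

    @property
    def counts(self) -> dict[str, int]:
        c = {r: 0 for r in RULE_IDS}
        for _, rule in self.removed:
            c[rule] = c.get(rule, 0) + 1
        return c

    @property
    def n_input(self) -> int:
        return len(self.kept) + len(self.removed)


def _failing_rule(
    s: GnssSample, last_kept: GnssSample | None, th: FilterThresholds
) -> str | None:
    if s.alt is None:
        return "R1"
    if s.acc > th.max_accuracy_m:
        return "R2"
    if s.accel_mag is not None and s.accel_mag < th.min_accel_mag:
        return "R3"
    if last_kept is not None:
        if (
            s.steps is not None
            and last_kept.steps is not None
            and s.steps - last_kept.steps == 0
        ):
            return "R4"
        dt = s.t - last_kept.t
        if dt <= 0:
            return "R5"
        if haversine_m((last_kept.lat, last_kept.lon), (s.lat, s.lon)) / dt > th.max_speed_mps:
            return "R6"
    return None


def apply_filters(
    trace: WalkTrace, thresholds: FilterThresholds | None = None
) -> FilterReport:
    """Apply the six exclusion rules to a raw trace.

    Returns a :class:`FilterReport` with the surviving trace and, for each
    removed sample, the first rule it failed. Idempotent: re-filtering the
    kept trace removes nothing.
    """
    if len(trace) == 0:
        raise ValueError("cannot filter an empty trace")
    th = thresholds or FilterThresholds()

    samples = trace.samples
    start = 0
    removed: list[tuple[int, str]] = []
    if th.trim_leading:
        # drop leading fixes until the GNSS lock reaches the start accuracy;
        # recorded under the pseudo-rule R0 so every sample is accounted for
        while start < len(samples) and samples[start].acc > th.start_accuracy_m:
            removed.append((start, "R0"))
            start += 1

    kept: list[GnssSample] = []
    for i in range(start, len(samples)):
        s = samples[i]
        rule = _failing_rule(s, kept[-1] if kept else None, th)
        if rule is None:
            kept.append(s)
        else:
            removed.append((i, rule))
    return FilterReport(kept=trace.with_samples(kept), removed=removed)
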