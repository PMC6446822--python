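"""Shared test helpers."""

from ridlsim.lifecycle import SexedCohort


def cohort_of(*entries: tuple[int, int, int, int]) -> SexedCohort:
    """Build a cohort from (r_copies, l_copies, sex, count) tuples."""
    c = SexedCohort.empty()
    for r, l, sex, n in entries:
        c.counts[r, l, sex] += n
    return c
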