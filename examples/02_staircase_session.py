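"""One 3-AFC, 3-down-1-up staircase session against a psychometric observer.

The observer answers correctly with probability 1/3 + (2/3 - lapse) x
logistic((log10 c - alpha)/beta); the staircase descends after three straight
correct choices and ascends after any error, until seven reversals (or a
floor / time / welfare stop).  The session threshold is the geometric mean
of the reversal concentrations, with imputation for incomplete sessions.
"""

import numpy as np

from olfthresh import (
    Observer,
    TerminationRules,
    default_ladder,
    run_session,
    session_threshold,
)

ladder = default_ladder()
rules = TerminationRules(reversals_required=7)
observer = Observer(alpha=-0.9, beta=0.15, lapse=0.02)  # midpoint at 12.6% odor

session = run_session(
    observer, ladder, rules, np.random.default_rng(7), dog="dog1", odor="C4"
)

print(f"trials run          : {len(session.trials)}")
print(f"termination         : {session.termination_reason}")
print(f"reversals (percent) : {[round(100 * r) for r in session.observed_reversals]}")

record = session_threshold(session, rules, impute=True)
print(f"log10 threshold     : {record.log10_threshold:.3f}")
print(f"threshold (percent) : {100 * record.threshold_fraction:.1f}%")
print()
print("The staircase oscillates around the concentration the observer gets")
print("~79% correct; the geometric mean of the reversal points estimates it.")
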