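"""Compute an equal-Z cut score for a single seven-judge panel summary.

The panel's mean lowest-pass mark is 60.43 (SE 8.34) and mean highest-fail
mark is 42.00 (SE 3.74).  The equal Z is the z-score at which the two
confidence intervals meet; the cut score sits at that point, and Phi(Z)
says how confident we are that the cut score is neither a pass nor a fail.
"""

from ezset import JudgmentSummary, confidence_from_z, ez_from_summary, threshold_check

summary = JudgmentSummary(x_l=42.00, x_h=60.43, se_l=3.74, se_h=8.34, n=7)
result = ez_from_summary(summary)

print(f"equal Z           : {result.z:.2f}")
print(f"cut score         : {result.cut_score:.2f}")
print(f"confidence (2dp Z): {confidence_from_z(result.z, round_z=True):.2f}%")
for flag in threshold_check(result):
    verdict = "reached" if flag.passed else "not reached"
    print(f"critical z {flag.critical_z:.2f}  : {verdict}")
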