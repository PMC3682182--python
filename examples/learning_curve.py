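"""Fit the exponential learning curve of one synthetic subject.

Generates a trial table (25 blocks of 16 trials per condition), excludes
reaction-time outliers, computes block inverse efficiency IE = mean RT /
accuracy, and fits y = a*exp(-b*x).
"""

from restdcm import GroundTruth, TaskDesign, behavior, synth

design = TaskDesign()
truth = GroundTruth()

trials = synth.gen_behavior(design, truth, seed=42)
curve = behavior.analyze_subject(trials)

print(f"trials generated:   {len(trials)}")
print(f"excluded trials:    {curve.excluded_trials}")
print(f"amplitude a:        {curve.a:.3f} s")
print(f"learning rate b:    {curve.b:.3f} per block")
print(f"block 1 IE (fit):   {curve.ie_fitted[0]:.3f} s")
print(f"block 25 IE (fit):  {curve.ie_fitted[-1]:.3f} s")
print()
print("a is the starting inverse-efficiency amplitude (lower IE = better");
print("performance); b is how fast performance improves per block.")
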