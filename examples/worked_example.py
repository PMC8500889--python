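"""The two-exemplar worked example: how s trades off averaging vs. recall.

Two stored exemplars share one cue pattern position; the probe is identical
to the first exemplar.  At s=1 every exemplar weighs equally and the model
predicts the plain mean of the stored criteria; as s shrinks the matching
exemplar dominates until, at s=0, the model reproduces its criterion
exactly.  This is why responses that verbatim-reproduce trained criteria
drag the estimated s toward 0.
"""

from exemplarmix import ExemplarMemory, ModelParams, predict_criterion, similarity

memory = ExemplarMemory(cues=[[0, 1], [1, 1]], criteria=[3.0, 7.0])
probe = [0, 1]

print("exemplars: [0,1] -> 3,  [1,1] -> 7;  probe [0,1] (identical to the first)")
for s in (1.0, 0.5, 0.1, 0.0):
    pred = predict_criterion(probe, memory, ModelParams(s))
    sim2 = similarity(probe, [1, 1], ModelParams(s))
    print(f"  s = {s:3.1f}: prediction = {pred:.4f}   (weight on mismatching exemplar: {sim2:.2f})")
print("at s=1 the prediction is the mean (5); at s=0 it is the matching criterion (3)")
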