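"""Generate the fear-conditioning trial table and inspect its structure.

Builds the reference design — 8 blocks of 24 trials in alternating
reinforcement / nonreinforcement contexts, simple and complex sounds in
block halves — assigns the reinforcement schedule, and prints the counts
that define the decoding analysis downstream.
"""

from fearpattern import DesignParams, assign_reinforcement, generate_design

design = assign_reinforcement(generate_design(DesignParams(seed=0)), seed=1)
df = design.to_frame()

print(f"total trials: {design.n_trials}")
print("\npresentations per stimulus (context x complexity x pair role):")
print(df.groupby(["context", "complexity", "pair_role"]).size().to_string())
print("\nreinforced trials per complexity (all CS+):")
print(df[df.reinforced == 1].groupby("complexity").size().to_string())
print("\nfirst four trials:")
print(df.head(4).to_string(index=False))

# Each of the 8 stimuli appears 24 times; 12 of the 24 CS+ per complexity
# carry the aversive US and are discarded before decoding, which is what
# creates the 24 CS- / 12 CS+ class imbalance the analysis must handle.
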