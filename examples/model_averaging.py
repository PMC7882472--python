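"""Full pipeline on a synthetic study: webs -> indices -> model averaging.

Runs every stage with a fixed seed and prints the model-averaging table for
the binomial specialist/generalist richness-ratio response: each term's
importance (number of delta-AICc < 6 candidate models containing it), its
conditional model-averaged estimate with 95% CI half-width, and
significance stars.  The synthetic truth contains a positive size x
connectivity interaction, which the fitted S:C term should recover.
"""

import tempfile

import pandas as pd

from fragweb import pipeline

with tempfile.TemporaryDirectory() as tmp:
    manifest = pipeline.run_all(
        tmp, config=pipeline.PipelineConfig(seed=1), synthetic=True
    )
    table = pd.read_csv(f"{tmp}/model_table.csv")

print(
    f"{manifest.n_fragments} fragments, {manifest.pooled_specimens} pooled specimens, "
    f"{manifest.excluded_specimens} excluded, {manifest.total_links} links"
)
ratio = table[table["response"] == "specialist_generalist"]
print("\nspecialist/generalist richness ratio (binomial GLM, conditional averaging):")
print(ratio.drop(columns=["response"]).round(3).fillna("").to_string(index=False))
print("\nA positive S:C estimate means connectivity favours specialists in")
print("large fragments but generalists in small ones, as configured in truth.")
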