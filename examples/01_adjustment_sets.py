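"""Query the study's causal graph for adjustment sets and implied
independences.

Loads the shipped hypothesised DAG for daily dog activity, asks which
covariates must be adjusted for when estimating the effect of breed size on
active minutes, and lists a few conditional independences the graph implies
(the checks run against data elsewhere in the pipeline).
"""

from caniact import implied_independences, load_dag, minimal_adjustment_sets
from caniact.pipeline import packaged_dag_path

dag = load_dag(packaged_dag_path())
print(f"DAG: {len(dag.nodes)} nodes ({len(dag.latent)} latent), {len(dag.edges)} edges")

for exposure in ("breed_size", "neuter_status", "season", "climate"):
    sets = minimal_adjustment_sets(dag, exposure, "active_minutes")
    pretty = [sorted(s.members) for s in sets] or "none possible"
    print(f"minimal backdoor adjustment sets for {exposure}: {pretty}")
# breed_size needs {location_type, owner_age}: both influence which dog an
# owner keeps AND how active the dog is.  Environmental exposures need no
# extra adjustment beyond variables already in the model.

claims = implied_independences(dag, observed_only=True)
print(f"\n{len(claims)} testable conditional independences implied; first three:")
for c in claims[:3]:
    cond = ", ".join(sorted(c.given)) or "nothing"
    print(f"  {c.x} independent of {c.y} given {cond}")
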