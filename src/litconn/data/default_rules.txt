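# Default connection-extraction rules, one per line: "name: pattern".
# Pattern elements: literals (| alternation, ? optional), REGION,
# REGION-LIST (regions joined by and/or/commas/"as well as"), GAP
# (up to five non-region tokens).  Regions of the first slot pair with
# regions of the second.
from_to: projection|projections|input|inputs|afferent|afferents from REGION-LIST to REGION-LIST
project_to: REGION-LIST GAP project|projects|projecting to REGION-LIST
receives_from: REGION receives|receive GAP projection|projections|input|inputs|afferent|afferents from REGION-LIST
sends_to: REGION-LIST send|sends|sent GAP projection|projections|efferent|efferents to REGION-LIST
efferents_from_to: efferent|efferents from REGION-LIST to REGION-LIST
pathway_from_to: pathway|pathways from REGION-LIST to REGION-LIST
innervates: REGION-LIST GAP innervate|innervates|innervated REGION-LIST
connections_between: connection|connections between REGION-LIST and REGION-LIST
connected_to: REGION is|are connected to|with REGION-LIST
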