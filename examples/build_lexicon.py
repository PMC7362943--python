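"""Build a phenotype term lexicon from an OBO ontology file.

Writes a small fixture ontology, builds the lexicon with the default
exclusions ("all", "left", "right" -- ontology labels that are hopeless
as free-text anchors), and shows which surface forms map to which terms.
"""

import tempfile
from pathlib import Path

from phenotweet import build_lexicon
from phenotweet.simdata import FIXTURE_TERMS, make_fixture_ontology

with tempfile.TemporaryDirectory() as tmp:
    obo = make_fixture_ontology(FIXTURE_TERMS, Path(tmp) / "fixture.obo")
    lexicon = build_lexicon(obo)

print(f"{len(lexicon)} surface forms from {len(lexicon.labels)} terms")
for key, term_ids in sorted(lexicon.entries.items()):
    print(f"  {key!r:26} -> {sorted(term_ids)}")
print(f"excluded forms: {sorted(lexicon.excluded_forms)}")

# Each line maps a normalized surface form (label or synonym, lowercased)
# to the ontology term ids bearing it; "all" never appears because it sits
# on the default exclusion list even though the ontology defines it.
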