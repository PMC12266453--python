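"""Embed lysine sites with a pluggable encoder and round-trip the table.

The deterministic mock encoder stands in for a protein language model: it
maps each residue to a feature vector keyed on (letter, position).  Real
encoders plug in through the same contract — `embed_sequence` returning
one row per residue.  The resulting table persists as a TSV site list
plus a raw float32 matrix.
"""

import tempfile
from pathlib import Path

import numpy as np

from ubisite import (batch_sites, embed_proteins, mock_encoder,
                     read_embeddings, write_embeddings)
from ubisite.synthetic import gen_toy_fasta

records, sites = gen_toy_fasta(n_proteins=3, length_range=(40, 60),
                               k_density=0.2, seed=4)
encoder = mock_encoder(dim=32, seed=0)

table = embed_proteins(encoder, records, sites, mode="full_sequence")
print(f"embedded {len(table)} sites -> feature matrix {table.features.shape}")

batches = batch_sites(table, batch_size=8)
print(f"{len(batches)} training batches; same-protein sites stay together:")
for b in batches:
    print("  ", sorted({table.sites[i].protein_id for i in b}),
          f"({len(b)} sites)")

stem = Path(tempfile.mkdtemp()) / "embeddings"
write_embeddings(table, stem)
back = read_embeddings(stem)
exact = np.array_equal(back.features,
                       table.features.astype(np.float32).astype(np.float64))
print(f"container round trip bit-exact at float32: {exact}")
# The row count equals the site count, and the reloaded matrix matches
# the written one exactly at the container's float32 precision.
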