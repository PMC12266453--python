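"""Enumerate lysine sites in a FASTA file and cut K-centred windows.

Builds a small synthetic FASTA, reads it back, lists every candidate
ubiquitination site (each lysine), and extracts a +/-5-residue window
around the first few — truncated at the termini, never padded.
"""

import tempfile
from pathlib import Path

from ubisite import (ProteinRecord, enumerate_lysines, extract_window,
                     read_fasta, redundancy_filter, write_fasta)
from ubisite.synthetic import gen_toy_fasta

records, sites = gen_toy_fasta(n_proteins=4, length_range=(30, 60),
                               k_density=0.15, seed=8)
fasta = Path(tempfile.mkdtemp()) / "toy.fasta"
write_fasta(records, fasta)

proteins = read_fasta(fasta)
print(f"{len(proteins)} proteins, {len(sites)} candidate lysine sites")
for protein in proteins[:2]:
    for site in enumerate_lysines(protein)[:3]:
        window = extract_window(protein.sequence, site.position, 5)
        print(f"  {site.protein_id} K{site.position}: window {window!r} "
              f"(length {len(window)})")

twin = ProteinRecord(id="TOY1_copy", sequence=proteins[0].sequence)
kept = redundancy_filter(proteins + [twin], identity_threshold=0.3)
print(f"redundancy filter on {len(proteins) + 1} records "
      f"(one duplicated): {len(kept)} kept")
# Each window covers at most 11 residues (5 either side of the lysine);
# shorter windows mean the site sits near a terminus.  The filter drops
# the duplicated record because its k-mer identity to the kept copy is 1.
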