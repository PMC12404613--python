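"""Read an SGA-dialect table and apply the two preprocessing filters.

Writes a small synthetic screen to disk in the released tab-separated
dialect, reads it back (gene names are the strain IDs up to the first
underscore), then (1) keeps only deleterious single mutants (fitness <= 1)
and (2) drops records where the Additive law would predict a negative
fitness (w_x + w_y < 1), so all laws are compared on one record set.
"""

import tempfile
from pathlib import Path

from neutrality.sga import filter_additive_domain, filter_deleterious, read_sga
from neutrality.synth import SynthConfig, generate_fitness_table, to_sga_tsv

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "screen.tsv"
    table = generate_fitness_table(
        SynthConfig(n_pairs=5000, law="product", noise_sigma=0.05, seed=2)
    )
    to_sga_tsv(table, path)

    records = read_sga(path)
    print(f"read {len(records)} records "
          f"({records.attrs['n_dropped_unparseable']} unparseable dropped)")
    records, rep1 = filter_deleterious(records)
    print(f"deleterious filter: dropped {rep1.n_dropped_fitness_gt1} "
          f"records with a single-mutant fitness above 1")
    records, rep2 = filter_additive_domain(records)
    print(f"additive-domain filter: dropped {rep2.n_dropped_additive_domain} "
          f"records with w_x + w_y < 1")
    print(f"retained {len(records)} records for the law comparison")
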