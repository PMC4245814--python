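"""Assemble an observed-data bundle from locally stored alignments.

The published survey sequences are deposited in GenBank; this package
does not download or bundle them.  If you have aligned them yourself
(one FASTA per locus, plus a popmap TSV mapping individual -> population
-> region and optionally an annotation TSV of coding intervals), this
script strips gap columns and writes the single JSON bundle that the
stats/ABC stages and the optional real-data test
(tests/test_acceptance.py) consume.

Usage:
  python examples/build_observed_bundle.py \
      --fasta 29789=aln/29789.fa --fasta 29997=aln/29997.fa ... \
      --popmap popmap.tsv [--annotation coding.tsv] \
      --out data/observed_bundle.json
"""

import argparse
from pathlib import Path

from invasionabc.seqdata import load_dataset, missing_fraction, strip_gap_columns, write_bundle

ap = argparse.ArgumentParser(description=__doc__)
ap.add_argument("--fasta", action="append", required=True,
                help="locus_id=path, repeatable (one per locus)")
ap.add_argument("--popmap", required=True)
ap.add_argument("--annotation", default=None)
ap.add_argument("--out", required=True)
args = ap.parse_args()

fastas = dict(item.split("=", 1) for item in args.fasta)
ds = load_dataset(fastas, args.popmap, args.annotation)
ds, removed = strip_gap_columns(ds)
Path(args.out).parent.mkdir(parents=True, exist_ok=True)
write_bundle(ds, args.out)
print(f"wrote {args.out}: {len(ds.individuals)} individuals, "
      f"{ds.total_length} bp after stripping {removed} gapped columns, "
      f"{100*missing_fraction(ds):.1f}% missing calls")
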