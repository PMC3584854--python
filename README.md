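# salsa

Local activity-site comparison for protein structures: align predicted
functional residues of related structures into a table of spatial
positions, derive a majority-rule consensus signature for a functional
subclass, and score a query protein's predicted site against that
signature with BLOSUM62, reported as a raw score and a percentage of the
perfect-match maximum. Useful for confirming, rejecting, or re-assigning
putative enzyme function annotations.

## What it does

1. **Read structures** (`salsa.structure_io`) — PDB files reduced to a
   residue-level model (author numbering preserved, side-chain centroids
   as representative points).
2. **Cut predicted sites** (`salsa.site_prediction`) — per-residue
   functional-likelihood rankings (TSV) cut at a top fraction
   (`ceil(fraction * N)` residues).
3. **Align locally** (`salsa.local_alignment`) — sequence-seeded iterative
   Kabsch superposition onto a reference, then nearest-centroid clustering
   of site residues into spatial positions (or import of an external
   aligned FASTA).
4. **Tabulate, derive, score** (`salsa.salsa_core`) — build the site table
   (uppercase = predicted, lowercase = unpredicted, `-` = gap), derive the
   consensus signature (majority rule, exact residue identity), and score
   query rows: unpredicted residues count as `X`, gaps incur a fixed
   penalty (default −3), the maximum is the signature's BLOSUM62 diagonal
   sum over actual codes, and percents are rounded to the nearest integer
   (ties away from zero).
5. **Simulate** (`salsa.synthetic_fixtures`) — seeded toy families with a
   planted site constellation, jitter, mutations, and matching ranking
   files, so the full pipeline is testable offline. Worked-example tables
   ship as packaged fixtures (`load_paper_fixture`).

## CLI

```sh
# generate a toy family with a planted 8-residue site
salsa simulate -o family --n-structures 5 --jitter 0.3 --seed 1

# predict sites, superpose, and build the site table
salsa table -s family/toy00.pdb -s family/toy01.pdb ... \
            -r family/toy00.rankings.tsv -r family/toy01.rankings.tsv ... \
            --top-fraction 0.16 -o out

# consensus signature from chosen reference rows
salsa consensus out/salsa_table.tsv --rows toy00,toy01,toy02,toy03

# score a query row against the consensus (and/or single rows)
salsa score out/salsa_table.tsv --query toy04 \
            --references toy00,toy01,toy02,toy03 --gap-penalty -3

# global-alignment sequence identity (sequences or FASTA files)
salsa identity HEAGAWGHEE PAWHEAE
```

Multi-chain PDB files require an explicit `--chain ID=CHAIN` choice.
`salsa table` echoes its effective configuration to `out/config.json`;
a YAML file passed via `--config` supplies flag defaults.

## Rankings TSV dialect

Tab-separated with header
`structure_id  chain  res_seq  icode  resname1  rank[  score]`;
ranks must form a permutation of 1..N. Rank is authoritative; the score
column is optional and carried through untouched.
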