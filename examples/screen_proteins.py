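"""Screen protein sequences for nosZ-like Cu_A and Cu_Z signatures.

Writes a small synthetic FASTA (three made-up sequences), applies the
200-800 aa length filter, scans kept sequences for the Cu_A binding motif
C-X3-C-X3-H, and counts histidines against the five-residue threshold of
the cupredoxin-like Cu_Z candidate.
"""

import tempfile
from pathlib import Path

from n2oflux import screen

fasta = """\
>candidate_1 synthetic nosZ-like fragment with CuA sites
MSDKLVEAAHCETTCSLAHGKVVADTPLAHHEGLDMKTWQSVNRAEFGHLI
CAAACAAAHVVTTGLNNDQPWLRKEYSMADFGHIKLMNPQRSTVWYAEDFG
HIKLMNPQRSTVWYAEDFGHIKLMNPQRSTVWYAEDFGHIKLMNPQRSTVW
YAEDFGHIKLMNPQRSTVWYAEDFGHIKLMNPQRSTVWYAEDFGHIKLMNP
QRSTVWYAEDFGHIKLMNPQRSTVWYAEDFGHIKLMNPQRSTVWYAEDFGH
>candidate_2 synthetic fragment, too short for the reference filter
MHHAHHLVCETC
>candidate_3 synthetic cupredoxin-like protein, histidine rich
MAHHEGKLVHDTPLAHHEGLDMKTWQSVNRAEFGHLIVVTTGLNNDQPWLR
KEYSMADFGHIKLMNPQRSTVWYAEDFGHIKLMNPQRSTVWYAEDFGHIKL
MNPQRSTVWYAEDFGHIKLMNPQRSTVWYAEDFGHIKLMNPQRSTVWYAED
FGHIKLMNPQRSTVWYAEDFGHIKLMNPQRSTVWYAEDFGHIKLMNPQRST
"""

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "candidates.faa"
    path.write_text(fasta)
    report = screen(path)  # defaults: keep 200-800 aa, histidine threshold 5

print(f"input records: {report.n_input}, kept: {report.n_kept}, "
      f"removed by length: {report.n_removed}")
print()
print(report.to_tsv(), end="")
print()
print("candidate_2 is dropped by the 200-800 aa filter; kept records are")
print("scanned for C-X3-C-X3-H (column cua_positions, 1-based starts) and")
print("his_flag marks sequences with at least five histidines.")
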