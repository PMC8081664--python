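#!/usr/bin/env python
"""Apply the universal nomenclature to lineage-specific gene aliases.

Maps the historical biochemical names (mesotocin, isotocin, vasopressin,
VT1..VT4 and friends) onto the evolution-based universal names and writes
the rename report.
"""

from pathlib import Path

from synorth.concordance import load_alias_table, rename

OUT = Path(__file__).resolve().parent.parent / "results"

EXAMPLES = [
    ("mammals", "OXT"), ("mammals", "AVP"), ("mammals", "OXTR"),
    ("mammals", "AVPR1A"), ("mammals", "AVPR1B"), ("mammals", "AVPR2"),
    ("birds", "MT"), ("birds", "MTR"), ("birds", "VT4"), ("birds", "VT1"),
    ("frogs", "MesoR"), ("frogs", "VasR"),
    ("fish", "IT"), ("fish", "ITR"), ("fish", "AVPR4"), ("fish", "AVPR2A"),
    ("sharks", "glumitocin"), ("lampreys", "VTR2B"), ("fish", "unnamed-locus"),
]


def main():
    aliases = load_alias_table()
    report = rename(EXAMPLES, aliases)
    OUT.mkdir(exist_ok=True)
    lines = ["lineage\told_name\tuniversal_name"]
    for (lineage, old), (_, new) in zip(EXAMPLES, report["records"]):
        lines.append(f"{lineage}\t{old}\t{new}")
    (OUT / "rename_report.tsv").write_text("\n".join(lines) + "\n")
    print(f"renamed {len(report['renamed'])} aliases; "
          f"{len(report['unmatched'])} passed through unmatched")
    for lineage, old, new in report["renamed"]:
        print(f"  {lineage:>8}: {old} -> {new}")
    for lineage, name in report["unmatched"]:
        print(f"  {lineage:>8}: {name} (no alias entry, passed through)")


if __name__ == "__main__":
    main()
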