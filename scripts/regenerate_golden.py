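"""Regenerate the checked-in golden outputs of the seeded demo run.

Runs the full `synth family -> profile -> consensus` demo through the CLI
into tests/data/golden/. Only run this deliberately, after verifying a
change in output format or pipeline behaviour is intended: the golden files
define the byte-level reproducibility contract.
"""

from pathlib import Path

from click.testing import CliRunner

from pocketsim.cli import cli

REPO = Path(__file__).resolve().parent.parent
GOLDEN = REPO / "tests" / "data" / "golden"
DEMO_SPEC = REPO / "examples" / "demo_family.yaml"


def run_demo(out_dir: Path) -> None:
    runner = CliRunner()
    steps = [
        ["synth", "family", "--spec", str(DEMO_SPEC), "--out-dir", str(out_dir)],
        ["profile",
         "--pdb-a", str(out_dir / "site0.pdb"), "--lig-a", "SBX",
         "--pdb-b", str(out_dir / "site1.pdb"), "--lig-b", "SBX",
         "--out", str(out_dir / "profile.tsv"), "--json", str(out_dir / "profile.json")],
        ["consensus",
         "--pdb", f"{out_dir / 'site0.pdb'}:SBX",
         "--pdb", f"{out_dir / 'site1.pdb'}:SBX",
         "--pdb", f"{out_dir / 'site2.pdb'}:SBX",
         "--out", str(out_dir / "consensus.pdb"),
         "--json", str(out_dir / "consensus.json")],
    ]
    for argv in steps:
        result = runner.invoke(cli, argv, catch_exceptions=False)
        assert result.exit_code == 0, result.output


if __name__ == "__main__":
    GOLDEN.mkdir(parents=True, exist_ok=True)
    run_demo(GOLDEN)
    print(f"wrote golden outputs to {GOLDEN}")
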