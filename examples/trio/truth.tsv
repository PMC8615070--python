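gene	role	designed_stage
TRIOA	driver	survivor
TRIOB	decoy	consequence
TRIOC	decoy	frequency
TRIOD	decoy	consensus
TRIOE	decoy	exclusivity-control-hit
TRIOF	decoy	exclusivity-case-incomplete
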