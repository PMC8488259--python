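The old house stood at the end of the quiet street.
A small garden grew beside the wooden door.
Every morning the birds sang in the tall trees.
People often stopped to watch the flowers in the warm sun.
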