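>glutelin rice glutelin storage protein
MASINRPIVFFTVCLFLLCDGSLAQQLLGQSTSQWQSSRRGSPRGCRFDRLQAFEPIRSVRSQAGTTEFFDVSNELFQCT
GVSVVRRVIEPRGLLLPHYTNGASLVYIIQGRGITGPTFPGCPETYQQQFQQSGQAQLTESQSQSHKFKDEHQKIHRFRQ
GDVIALPAGVAHWCYNDGEVPVVAIYVTDINNGANQLDPRQRDFLLAGNKRNPQAYRREVEEWSQNIFSGFSTELLSEAF
GISNQVARQLQCQNDQRGEIVRVERGLSLLQPYASLQEQEQGQMQSREHYQEGGYQQSQYGSGCPNGLDETFCTMRVRQN
IDNPNRADTYNPRAGRVTNLNSQNFPILNLVQMSAVKVNLYQNALLSPFWNINAHSIVYITQGRAQVQVVNNNGKTVFNG
ELRRGQLLIVPQHYVVVKKAQREGCAYIAFKTNPNSMVSHIAGKSSIFRALPTDVLANAYRISREEAQRLKHNRGDEFGA
FTPLQYKSYQDVYNVAESS
>prolamin rice prolamin storage protein
MKIIFFFALLAEAACSASAQFDAVTQVYRQYQLQQQMLSPCGEFVRQQCSTVATPFFQSPVFQLRNCQVMQQQCCQQLRM
IAQQSHCQAISSVQAIVQQLQLQQFSGVYFDQAQAQAQAMLGLNLPSICGIYPSYNTVPEIPTVGGIWY
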