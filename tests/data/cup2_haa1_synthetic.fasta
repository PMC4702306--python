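>Cup2_synthetic synthetic stand-in peptide, 225 residues (not the real Cup2 sequence)
TLFMSVWIKPGVSKGEWHGNFYCEQTRHCLQMELPAVIPLEMWRDEWDQYKDLSAFNEYY
CMIGTCNLYVINVMVNTDYMVGMLQCENFIFNLVHYHILKIETNLMKRAMMCEVRMIWCY
DEDSGTKSFEHEDCCGKNPGADFTEDTCQRKPIDAVNAQWINEVPVADLDTLTNGSWLIF
HEPGMEGRNQKNRWECDEGHEIKLMTVPGDINCRLKWMTRMVNNR
>Haa1_synthetic synthetic stand-in peptide, 694 residues (not the real Haa1 sequence)
TVFVNVWIKPCQSKGEWHGNWYCEQTRHCLEMELQHVIPLEDSDDEWDTYDDLFTSVPFI
VMDGTRNTMMLTLNIYVEMLMKNYWISSFIDLWEMEHIYWWYKEAESRREWEHWKKYFQY
DVVDLTKGFGHVDVCSKDDSWPVYYGTAQEGPNMKCNSCRQNDVHFKDADTPNFGRWCYI
CQMTMGVRYQLARWYGTDSNDEKKGHLSRFDDCNWPWNRSEWMEQNSMVGCYKFQYDTYP
VLSSNWCDYGSDKGKNGERMLKEELYWFDIDYDNLCWEHPSIMTCVVDWPTDAPGFLRDR
STWEHYPHGNMPPYYGDAGYEQATNLSEYRTIIGFYPTQGKFSEFFEQNCWENAWVPDNT
VTMSKRDGCENNDLKTNYNAQQLGAFFYTFLEAYIAYDPCWVSDFLKPPNQDDRSIWSCD
LIYMAFDYEHEKLQMNVHKFQIVSIMEMFQFTKLDGIDCYYNGPDEKRQSNDGYWHMSCV
RTPNCGFHYRKDNMRNMGKILGHKFRFWFYKYHGHEGYRGHCRANEKQTPPMWIWFALIS
GEIVYLVPVYDHPMVFRDGPWSSHQLENTMGTMYDWGHGEQGIMIPKWSQVLWIDKPPHF
WFDHVFQDMAAILCTRGHMIYPVVQCSNFVEWHNLFSYHLLETTIHMQVRFHHDQKNHIR
QTRFLVQQTFALPAAWMRVMYNHCWLAGMVVALD
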