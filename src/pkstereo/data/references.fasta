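>AT curated reference consensus (300 aa)
SMHNSICKLGCNDQHECRATGCKADCKLCEHIKFRTKSRAGPKFGFVARCFMWDEDQVDF
DMVQRQQFENQPNEVITQDNDSSMDGSQKTHHVIMLCLPHMSPQASIQSRCKLIVPMFFK
CWKQMDMFIRHENQYDDTMGSDLLNVEYPTQDRGFIEGLKYMPMWIQPDKLSTSNTMVAY
TRYHSHCRMEVLICEIHAFHFGALHCCPVAHFLKNIMNELWPKISRGRWCRRFGSCDPGG
FYMMMLQPEWERGPPNMGEHIDLWACTEASLMYTCISMPEELMWKCRTHRYKFGPLRITT
>KR curated reference consensus (260 aa)
QWYVFQANYEHDSYEFHSSWYPNLEHQILGVKKTKNGNCKDDQPEYMTEKQHTAVWWNRD
KAEQMPLWLNMFAILALQACERIGVQICLCHLDDMPKDPPTYIDDVGPRGYICYTKATNT
QALDQAHLHPMTHLGRYVNFFNESFIIILHPSKIVYYCIMNLNVFTEPCRFRRPMWPHAF
LPYHCAFKGMCDVDEDHRVKFQYLIDVTELLSQIVCTQATFTLTKQYDGVNNTYYCTTKS
AIRCEFIMMVGQPDRKEYAV
>DH curated reference consensus (280 aa)
RMIYDPELMYQKHERYNFHKDPYKWPGQTVTVCYTAPLKDWEMEHAVTGSLARPICQNYI
TYPSQLWLPNYAMFKEYIWMPKILFPTMEESQCWVSADNMSNNDFHDCKIEPWIHAKDIW
FSMMHRCGLGLYCEFKQCQWSCLKERVDVARINQPDPRYFQVSLCVMQYDIRCPWMGCKS
IMTKFSCWAIFVAPRMHGSLDRAQETSWYDFKWYGSIHDRQKNKENRDGNFWCCVSYPVC
DVSARPGLNYDPYLTPNIWVSPAINMPEPAHIRTHCRNHE
>ER curated reference consensus (310 aa)
LNRYPQRCDRQEMAHTEWNEWYTKPLHHFIWDGYWILILKQLGYLCSAGRRELATYWMTD
MWNNPFRRVASEGMIWRLMESRWEDEFVEIQPEIIVTVGTEHVNQNQGPLELRSRHGYAT
DFTPRSQHPWDTKFHKNRLAFKVPHWARKIAQFSFNEEQDDQQRACRFIQVSSIAVAGFF
TPVKAWPYKWQFFDWVTGQVPNYPDQHYMMCCVGCEFIPRQKILANALYVWSECDVKDMC
ASEFMWGFIYPAPQDMQRDFSSTVVGCMGFPIKFWWCMQPVQFCYMMQHETRHSHPAGPG
TIIGQGNGES
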