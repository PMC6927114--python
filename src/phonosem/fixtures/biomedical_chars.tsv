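# char	primary_radical	readings	ids
# Biomedical demonstration characters with primary radical, pinyin
# reading(s) and (simplified) Ideographic Description Sequences.
# Decompositions keep exactly the components relevant to the
# phono-semantic analysis of each character.
病	疒	bìng	⿸疒丙
痨	疒	láo	⿸疒劳
痛	疒	tòng	⿸疒甬
肝	月	gān	⿰月干
胸	月	xiōng	⿰月匈
脑	月	nǎo	⿰月凶
胃	月	wèi	⿱田月
心	心	xīn	心
害	宀	hài	⿱宀⿱丰口
徒	彳	tú	⿰彳走
症	疒	zhèng	⿸疒正
# components
疒	疒	nè	疒
丙	一	bǐng	丙
劳	力	láo	劳
甬	用	yǒng	甬
干	干	gān;gàn	干
匈	勹	xiōng	⿹勹凶
凶	凵	xiōng	凶
月	月	yuè	月
田	田	tián	田
宀	宀	mián	宀
丰	丨	fēng	丰
口	口	kǒu	口
彳	彳	chì	彳
走	走	zǒu	⿱土龰
土	土	tǔ	土
正	一	zhèng	正
一	一	yī	一
力	力	lì	力
用	用	yòng	用
凵	凵	kǎn	凵
勹	勹	bāo	勹
# translated biomedical terms: 帕金森氏症 (Parkinson's), 阿司匹林 (aspirin)
帕	巾	pà	⿰巾白
金	金	jīn	金
森	木	sēn	⿱木⿰木木
氏	氏	shì	氏
阿	阝	ā	⿰阝可
司	口	sī	司
匹	匚	pǐ	匹
林	木	lín	⿰木木
木	木	mù	木
巾	巾	jīn	巾
白	白	bái	白
阝	阝	fǔ	阝
可	口	kě	可
匚	匚	fāng	匚
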